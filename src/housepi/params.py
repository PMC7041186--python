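"""Model parameters, validation, and derived economic indices.

All epidemiological quantities are daily probabilities in [0, 1]; "hatted"
variants apply to members of bankrupt households (money <= 0), where loss of
nutritional and treatment resources elevates transmission.  Economic
quantities are in money units per day (production ``P_p``, consumption
``C_c``) or per treatment course (``C_t``).

The same parameter set drives both the discrete agent-based engine and the
continuous switched-ODE engine.  The correspondence between the daily
probabilities of the discrete model and the rates of the continuous model is
controlled by :attr:`ModelParams.rate_conversion`:

``identity``
    use the tabulated daily probabilities verbatim as daily rates;
``exact_exponential``
    convert the recovery probabilities through the exponential-waiting-time
    map ``r = -ln(1 - p)`` (recovery only: equating the two engines' basic
    reproduction numbers needs only the recovery rates adjusted, since the
    per-pair transmission probabilities are already small enough that the
    probability/rate distinction is second order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

__all__ = [
    "EpiParams",
    "EconParams",
    "Demography",
    "TreatmentPolicy",
    "ModelParams",
    "compute_cpr",
    "compute_tci",
    "c_c_from_cpr",
    "c_t_from_tci",
    "rate_from_daily_probability",
    "probability_from_rate",
]

RateConversion = Literal["identity", "exact_exponential"]
MoneyScale = Literal["per_household", "per_capita"]


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {value!r}")


@dataclass(frozen=True)
class EpiParams:
    """Daily epidemiological probabilities for producers (p) and consumers (c).

    ``beta``: population-wide (global) transmission; ``iota``: within-household
    transmission; ``gamma``: recovery untreated; ``gamma_plus``: recovery under
    treatment.  ``*_hat`` variants apply while the susceptible's household is
    bankrupt.
    """

    beta_p: float = 0.3
    beta_c: float = 0.5
    beta_hat_p: float = 0.4
    beta_hat_c: float = 0.7
    iota_p: float = 0.03
    iota_c: float = 0.05
    iota_hat_p: float = 0.04
    iota_hat_c: float = 0.07
    gamma_p: float = 0.1
    gamma_c: float = 0.1
    gamma_plus_p: float = 0.5
    gamma_plus_c: float = 0.5

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            _check_prob(name, getattr(self, name))
        for x in "pc":
            if getattr(self, f"beta_hat_{x}") < getattr(self, f"beta_{x}"):
                raise ValueError(f"beta_hat_{x} < beta_{x}: bankruptcy cannot reduce transmission")
            if getattr(self, f"iota_hat_{x}") < getattr(self, f"iota_{x}"):
                raise ValueError(f"iota_hat_{x} < iota_{x}: bankruptcy cannot reduce transmission")
            if getattr(self, f"gamma_plus_{x}") < getattr(self, f"gamma_{x}"):
                raise ValueError(f"gamma_plus_{x} < gamma_{x}: treatment cannot slow recovery")

    def as_rates(self, conversion: RateConversion = "identity") -> "EpiParams":
        """Return the parameter set to be used as continuous daily rates."""
        if conversion == "identity":
            return self
        if conversion == "exact_exponential":
            return replace(
                self,
                gamma_p=rate_from_daily_probability(self.gamma_p),
                gamma_c=rate_from_daily_probability(self.gamma_c),
                gamma_plus_p=rate_from_daily_probability(self.gamma_plus_p),
                gamma_plus_c=rate_from_daily_probability(self.gamma_plus_c),
            )
        raise ValueError(f"unknown rate conversion {conversion!r}")


@dataclass(frozen=True)
class EconParams:
    """Household economics: production, consumption, treatment cost, seed money.

    ``P_p`` is the net daily production of one healthy producer, ``C_c`` the
    net daily cost of one consumer, ``C_t`` the one-course treatment cost and
    ``M0`` the initial money per household.
    """

    P_p: float = 50.0
    C_c: float = 30.0
    C_t: float = 250.0
    M0: float = 500.0

    def __post_init__(self) -> None:
        if self.P_p <= 0:
            raise ValueError("P_p must be positive (zero production capacity is undefined)")
        if self.C_c < 0:
            raise ValueError("C_c must be non-negative")
        if self.C_t < 0:
            raise ValueError("C_t must be non-negative")


@dataclass(frozen=True)
class Demography:
    """Household composition scheme.

    Producers per household are supported on ``producers_range`` and
    consumers on ``consumers_range``; at the defaults the implied population
    is ``500 * (2 + 3) = 2500`` with a 40%/60% producer/consumer split.
    """

    n_households: int = 500
    producers_range: tuple[int, int] = (1, 4)
    consumers_range: tuple[int, int] = (0, 7)
    mean_producers: float = 2.0
    mean_consumers: float = 3.0

    def __post_init__(self) -> None:
        if self.n_households < 1:
            raise ValueError("n_households must be >= 1")
        for name in ("producers_range", "consumers_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"invalid {name}: {(lo, hi)}")
        if not self.producers_range[0] <= self.mean_producers <= self.producers_range[1]:
            raise ValueError("mean_producers outside producers_range")
        if not self.consumers_range[0] <= self.mean_consumers <= self.consumers_range[1]:
            raise ValueError("mean_consumers outside consumers_range")

    @property
    def mean_household_size(self) -> float:
        return self.mean_producers + self.mean_consumers

    @property
    def population_size(self) -> float:
        """Implied total population N (2500 at defaults)."""
        return self.n_households * self.mean_household_size

    @property
    def producer_fraction(self) -> float:
        return self.mean_producers / self.mean_household_size


@dataclass(frozen=True)
class TreatmentPolicy:
    """Fractions of newly infected producers/consumers designated for treatment."""

    T_p: float = 0.0
    T_c: float = 0.0

    def __post_init__(self) -> None:
        _check_prob("T_p", self.T_p)
        _check_prob("T_c", self.T_c)


@dataclass(frozen=True)
class ModelParams:
    """Single source of truth for both simulation engines.

    ``money_scale`` selects the units of the collective money variable in the
    continuous model: ``per_household`` divides the aggregate daily flows by
    the number of households, so that ``M_h`` is the purse of the average
    household and is directly comparable with the agent-based model's
    per-household ``M0 = 500``; ``per_capita`` divides by the population size
    N instead (the flows are then per capita while ``M0`` remains a
    per-household quantity, which makes bankruptcy roughly |h| times harder
    to reach).
    """

    epi: EpiParams = field(default_factory=EpiParams)
    econ: EconParams = field(default_factory=EconParams)
    rate_conversion: RateConversion = "identity"
    money_scale: MoneyScale = "per_household"

    def __post_init__(self) -> None:
        if self.rate_conversion not in ("identity", "exact_exponential"):
            raise ValueError(f"unknown rate_conversion {self.rate_conversion!r}")
        if self.money_scale not in ("per_household", "per_capita"):
            raise ValueError(f"unknown money_scale {self.money_scale!r}")

    def ode_rates(self) -> EpiParams:
        """Epidemiological parameters as continuous rates for the ODE engine."""
        return self.epi.as_rates(self.rate_conversion)


def compute_cpr(econ: EconParams, demog: Demography) -> float:
    """Consumption-to-production ratio of the average household.

    ``CPR = (C_c * mean_consumers) / (P_p * mean_producers)``; CPR > 1 means
    the average household loses money daily even with all producers healthy.
    """
    production = econ.P_p * demog.mean_producers
    if production <= 0:
        raise ValueError("average household has zero production capacity; CPR undefined")
    return econ.C_c * demog.mean_consumers / production


def compute_tci(econ: EconParams, demog: Demography) -> float:
    """Treatment-cost index: one treatment in days of average-household income.

    ``TCI = C_t / (P_p * mean_producers)`` (``C_t / (2 P_p)`` at defaults).
    """
    production = econ.P_p * demog.mean_producers
    if production <= 0:
        raise ValueError("average household has zero production capacity; TCI undefined")
    return econ.C_t / production


def c_c_from_cpr(cpr: float, econ: EconParams, demog: Demography) -> float:
    """Per-consumer daily cost C_c giving the requested CPR (inverse of compute_cpr)."""
    if cpr < 0:
        raise ValueError("CPR must be non-negative")
    if demog.mean_consumers <= 0:
        raise ValueError("mean_consumers must be positive to invert CPR")
    return cpr * econ.P_p * demog.mean_producers / demog.mean_consumers


def c_t_from_tci(tci: float, econ: EconParams, demog: Demography) -> float:
    """Treatment cost C_t giving the requested TCI (inverse of compute_tci)."""
    if tci < 0:
        raise ValueError("TCI must be non-negative")
    return tci * econ.P_p * demog.mean_producers


def rate_from_daily_probability(p: float) -> float:
    """Continuous daily rate equivalent to a one-day event probability.

    Under an exponential waiting time, an event with daily rate r occurs
    within one day with probability ``1 - exp(-r)``; inverting gives
    ``r = -ln(1 - p)``.
    """
    if not 0.0 <= p < 1.0:
        raise ValueError(f"daily probability must lie in [0, 1), got {p!r}")
    return -math.log1p(-p)


def probability_from_rate(r: float) -> float:
    """One-day event probability of a process with continuous daily rate r."""
    if r < 0:
        raise ValueError(f"rate must be non-negative, got {r!r}")
    return -math.expm1(-r)
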