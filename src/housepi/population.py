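"""Stochastic synthesis of the household population for the agent-based model.

Households are built from Bernoulli "arrival" draws: with ``k`` possible
arrivals beyond the guaranteed minimum, the count on support ``[lo, hi]``
with mean ``m`` is ``lo + Binomial(hi - lo, (m - lo)/(hi - lo))``.  At the
default demography this gives producers ``1 + Binomial(3, 1/3)`` (support
1-4, mean 2) and consumers ``Binomial(7, 3/7)`` (support 0-7, mean 3).

The population is stored column-wise (role, disease state and household index
per individual; money per household) so the daily simulator can update it
with vectorised draws; :class:`Individual` and :class:`Household` are light
record views over those columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .params import Demography

__all__ = [
    "S",
    "I_UNTREATED",
    "I_TREATED",
    "R",
    "STATE_NAMES",
    "Individual",
    "Household",
    "HouseholdPopulation",
    "synthesize_population",
    "seed_index_case",
]

# Disease states (int8 codes used throughout the ABM).
S, I_UNTREATED, I_TREATED, R = 0, 1, 2, 3
STATE_NAMES = {S: "S", I_UNTREATED: "I_untreated", I_TREATED: "I_treated", R: "R"}
_STATE_CODES = {v: k for k, v in STATE_NAMES.items()}


@dataclass(frozen=True)
class Individual:
    role: str  # "producer" | "consumer"
    disease_state: str  # "S" | "I_untreated" | "I_treated" | "R"
    household_id: int


@dataclass(frozen=True)
class Household:
    id: int
    members: tuple[Individual, ...]
    money: float

    @property
    def n_producers(self) -> int:
        return sum(m.role == "producer" for m in self.members)

    @property
    def n_consumers(self) -> int:
        return sum(m.role == "consumer" for m in self.members)


@dataclass
class HouseholdPopulation:
    """Columnar population state shared by the synthesiser and the ABM.

    ``household_of[i]`` is the household index of individual ``i``;
    ``is_producer[i]`` their immutable role; ``state[i]`` their disease state
    code; ``money[h]`` the signed purse of household ``h``.
    """

    household_of: np.ndarray  # int32, shape (n_individuals,)
    is_producer: np.ndarray  # bool, shape (n_individuals,)
    state: np.ndarray  # int8, shape (n_individuals,)
    money: np.ndarray  # float64, shape (n_households,)
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        n = len(self.household_of)
        if not (len(self.is_producer) == len(self.state) == n):
            raise ValueError("per-individual columns must have equal length")
        if self.household_of.min(initial=0) < 0 or (
            n and self.household_of.max() >= len(self.money)
        ):
            raise ValueError("household indices out of range")

    @property
    def n_households(self) -> int:
        return len(self.money)

    @property
    def n_individuals(self) -> int:
        return len(self.state)

    @property
    def n_producers(self) -> int:
        return int(self.is_producer.sum())

    @property
    def n_consumers(self) -> int:
        return int((~self.is_producer).sum())

    def producers_per_household(self) -> np.ndarray:
        return np.bincount(
            self.household_of[self.is_producer], minlength=self.n_households
        )

    def consumers_per_household(self) -> np.ndarray:
        return np.bincount(
            self.household_of[~self.is_producer], minlength=self.n_households
        )

    def copy(self) -> "HouseholdPopulation":
        return HouseholdPopulation(
            household_of=self.household_of.copy(),
            is_producer=self.is_producer.copy(),
            state=self.state.copy(),
            money=self.money.copy(),
            rng_seed=self.rng_seed,
        )

    def households(self) -> Iterator[Household]:
        """Yield record views (convenience; not used on the hot path)."""
        order = np.argsort(self.household_of, kind="stable")
        bounds = np.searchsorted(
            self.household_of[order], np.arange(self.n_households + 1)
        )
        for h in range(self.n_households):
            idx = order[bounds[h] : bounds[h + 1]]
            members = tuple(
                Individual(
                    role="producer" if self.is_producer[i] else "consumer",
                    disease_state=STATE_NAMES[int(self.state[i])],
                    household_id=h,
                )
                for i in idx
            )
            yield Household(id=h, members=members, money=float(self.money[h]))

    # -- persistence -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """One row per individual: household_id, role, disease_state, money."""
        return pd.DataFrame(
            {
                "household_id": self.household_of.astype(int),
                "role": np.where(self.is_producer, "producer", "consumer"),
                "disease_state": [STATE_NAMES[int(s)] for s in self.state],
                "money": self.money[self.household_of],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "HouseholdPopulation":
        hh = frame["household_id"].to_numpy(dtype=np.int32)
        n_households = int(hh.max()) + 1 if len(hh) else 0
        money = np.zeros(n_households)
        # last seen value wins; rows of one household carry identical money
        money[hh] = frame["money"].to_numpy(dtype=float)
        return cls(
            household_of=hh,
            is_producer=(frame["role"] == "producer").to_numpy(),
            state=np.array(
                [_STATE_CODES[s] for s in frame["disease_state"]], dtype=np.int8
            ),
            money=money,
        )

    @classmethod
    def from_csv(cls, path) -> "HouseholdPopulation":
        return cls.from_frame(pd.read_csv(path))


def _bounded_binomial(
    rng: np.random.Generator, n: int, lo: int, hi: int, mean: float
) -> np.ndarray:
    """lo + Binomial(hi - lo, (mean - lo)/(hi - lo)), or a constant column."""
    if hi == lo:
        return np.full(n, lo, dtype=np.int64)
    p = (mean - lo) / (hi - lo)
    return lo + rng.binomial(hi - lo, p, size=n)


def synthesize_population(
    demog: Demography, m0: float, seed: int | np.random.SeedSequence
) -> HouseholdPopulation:
    """Draw a household population; identical seeds give identical populations.

    Every individual starts susceptible and every household starts with
    money ``m0``.
    """
    rng = np.random.default_rng(seed)
    lo_p, hi_p = demog.producers_range
    lo_c, hi_c = demog.consumers_range
    producers = _bounded_binomial(rng, demog.n_households, lo_p, hi_p, demog.mean_producers)
    consumers = _bounded_binomial(rng, demog.n_households, lo_c, hi_c, demog.mean_consumers)

    sizes = producers + consumers
    household_of = np.repeat(np.arange(demog.n_households, dtype=np.int32), sizes)
    # within a household, producers are listed first
    is_producer = np.concatenate(
        [
            np.concatenate([np.ones(p, dtype=bool), np.zeros(c, dtype=bool)])
            for p, c in zip(producers, consumers)
        ]
    )
    return HouseholdPopulation(
        household_of=household_of,
        is_producer=is_producer,
        state=np.zeros(len(household_of), dtype=np.int8),
        money=np.full(demog.n_households, float(m0)),
        rng_seed=seed if isinstance(seed, int) else None,
    )


def seed_index_case(
    pop: HouseholdPopulation, seed: int | np.random.SeedSequence
) -> HouseholdPopulation:
    """Return a copy with exactly one producer infected (untreated), all else S.

    Idempotent: any pre-existing infections are cleared first, so applying
    the operation twice still leaves a single index case.
    """
    producers = np.flatnonzero(pop.is_producer)
    if len(producers) == 0:
        raise ValueError("population has no producers to seed the outbreak")
    rng = np.random.default_rng(seed)
    out = pop.copy()
    out.state[:] = S
    out.state[rng.choice(producers)] = I_UNTREATED
    return out
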