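"""Discrete-time (1-day) stochastic household epidemic simulator.

Each simulated day applies, in order:

1. recovery draws for every infective (probability ``gamma`` untreated,
   ``gamma_plus`` treated);
2. infection draws for every susceptible, using start-of-day infective
   counts and start-of-day household solvency;
3. treatment assignment for the day's new infectives: an individual is
   treated iff a Bernoulli(``T_role``) coverage draw succeeds AND their
   household still has money > 0, in which case the one-time cost ``C_t``
   is debited immediately (onset is the only opportunity to treat);
4. the household economy update: each healthy (S or R) producer adds
   ``P_p``, each consumer costs ``C_c``; sick producers neither produce
   nor consume.

The per-susceptible composite infection probability combines independent
exposure to every infective outside the household (per-pair probability
``beta / (N - 1)``) and to every infective inside it (probability ``iota``),
with the hatted (elevated) values whenever the susceptible's own household
was bankrupt (money <= 0) at the start of the day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import Demography, EpiParams, ModelParams, TreatmentPolicy
from .population import (
    I_TREATED,
    I_UNTREATED,
    R,
    S,
    HouseholdPopulation,
    seed_index_case,
    synthesize_population,
)

__all__ = [
    "AbmDayRecord",
    "AbmResult",
    "MonteCarloSummary",
    "infection_probability",
    "advance_day",
    "run_abm",
    "monte_carlo_burden",
]


@dataclass(frozen=True)
class AbmDayRecord:
    """End-of-day census plus the day's money ledger entries."""

    day: int
    s_p: int
    i_untreated_p: int
    i_treated_p: int
    r_p: int
    s_c: int
    i_untreated_c: int
    i_treated_c: int
    r_c: int
    cumulative_infections_p: int
    cumulative_infections_c: int
    n_bankrupt_households: int
    total_money: float
    production: float
    consumption: float
    treatment_spend: float
    new_infections: int
    new_treated: int
    hatted_draws: int  # susceptible-days evaluated with bankrupt (hatted) rates

    @property
    def n_individuals(self) -> int:
        return (
            self.s_p + self.i_untreated_p + self.i_treated_p + self.r_p
            + self.s_c + self.i_untreated_c + self.i_treated_c + self.r_c
        )


@dataclass
class AbmResult:
    trajectory: list[AbmDayRecord]
    final_burden_p: int
    final_burden_c: int
    seed: int | None
    truncated: bool = False
    population: HouseholdPopulation | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.trajectory])


@dataclass(frozen=True)
class MonteCarloSummary:
    mean_burden_p: float
    mean_burden_c: float
    se_burden_p: float
    se_burden_c: float
    burdens_p: np.ndarray
    burdens_c: np.ndarray
    n_reps: int


def infection_probability(
    role: str,
    solvent: bool,
    n_inf_outside: int,
    n_inf_household: int,
    params: EpiParams,
    n_population: int,
) -> float:
    """Composite one-day infection probability for a single susceptible.

    ``1 - (1 - beta/(N-1))**n_outside * (1 - iota)**n_household`` with the
    hatted parameter pair substituted when the susceptible's household is
    bankrupt.  Monotone non-decreasing in both exposure counts.
    """
    if n_inf_outside < 0 or n_inf_household < 0:
        raise ValueError("infective counts must be non-negative")
    if n_population < 2:
        raise ValueError("population must contain at least 2 individuals")
    suffix = "p" if role == "producer" else "c"
    prefix = "" if solvent else "hat_"
    beta = getattr(params, f"beta_{prefix}{suffix}")
    iota = getattr(params, f"iota_{prefix}{suffix}")
    escape = (1.0 - beta / (n_population - 1)) ** n_inf_outside
    escape *= (1.0 - iota) ** n_inf_household
    return 1.0 - escape


def _census(pop: HouseholdPopulation) -> dict[str, int]:
    out = {}
    for role, mask in (("p", pop.is_producer), ("c", ~pop.is_producer)):
        st = pop.state[mask]
        out[f"s_{role}"] = int((st == S).sum())
        out[f"i_untreated_{role}"] = int((st == I_UNTREATED).sum())
        out[f"i_treated_{role}"] = int((st == I_TREATED).sum())
        out[f"r_{role}"] = int((st == R).sum())
    return out


def _advance_day_inplace(
    pop: HouseholdPopulation,
    params: ModelParams,
    policy: TreatmentPolicy,
    rng: np.random.Generator,
    day: int,
    cum_p: int,
    cum_c: int,
) -> tuple[AbmDayRecord, int, int]:
    """One simulated day, mutating ``pop``; returns the record and new cumulatives."""
    epi = params.epi
    econ = params.econ
    n = pop.n_individuals
    state0 = pop.state  # mutated in place below; snapshots taken as needed

    # --- start-of-day exposure snapshot ---
    infective = (state0 == I_UNTREATED) | (state0 == I_TREATED)
    n_inf_total = int(infective.sum())
    inf_per_hh = np.bincount(
        pop.household_of[infective], minlength=pop.n_households
    )
    bankrupt_hh = pop.money <= 0.0

    # --- 1. recoveries (probability gamma / gamma_plus by role) ---
    u = rng.random(n)
    gamma = np.where(pop.is_producer, epi.gamma_p, epi.gamma_c)
    gamma_plus = np.where(pop.is_producer, epi.gamma_plus_p, epi.gamma_plus_c)
    recover = ((state0 == I_UNTREATED) & (u < gamma)) | (
        (state0 == I_TREATED) & (u < gamma_plus)
    )
    pop.state[recover] = R

    # --- 2. infections from start-of-day counts and solvency ---
    susceptible = state0 == S  # recoveries cannot have created susceptibles
    hatted_draws = 0
    new_idx = np.empty(0, dtype=np.int64)
    if n_inf_total > 0 and susceptible.any():
        idx = np.flatnonzero(susceptible)
        hh = pop.household_of[idx]
        n_hh_inf = inf_per_hh[hh]
        n_out_inf = n_inf_total - n_hh_inf
        bankrupt = bankrupt_hh[hh]
        prod = pop.is_producer[idx]
        beta = np.where(
            bankrupt,
            np.where(prod, epi.beta_hat_p, epi.beta_hat_c),
            np.where(prod, epi.beta_p, epi.beta_c),
        )
        iota = np.where(
            bankrupt,
            np.where(prod, epi.iota_hat_p, epi.iota_hat_c),
            np.where(prod, epi.iota_p, epi.iota_c),
        )
        p_inf = 1.0 - (1.0 - beta / (n - 1)) ** n_out_inf * (1.0 - iota) ** n_hh_inf
        hatted_draws = int(bankrupt.sum())
        new_idx = idx[rng.random(len(idx)) < p_inf]
        pop.state[new_idx] = I_UNTREATED

    # --- 3. treatment at onset: coverage draw AND affordability, cost debited ---
    treatment_spend = 0.0
    n_treated = 0
    if len(new_idx):
        t_cov = np.where(pop.is_producer[new_idx], policy.T_p, policy.T_c)
        wants = rng.random(len(new_idx)) < t_cov
        for i, w in zip(new_idx, wants):  # sequential: each purchase depletes money
            if w and pop.money[pop.household_of[i]] > 0.0:
                pop.state[i] = I_TREATED
                pop.money[pop.household_of[i]] -= econ.C_t
                treatment_spend += econ.C_t
                n_treated += 1

    # --- 4. economy: healthy producers produce, all consumers consume ---
    healthy_producer = pop.is_producer & ((pop.state == S) | (pop.state == R))
    prod_per_hh = np.bincount(
        pop.household_of[healthy_producer], minlength=pop.n_households
    )
    cons_per_hh = pop.consumers_per_household()
    production = econ.P_p * float(prod_per_hh.sum())
    consumption = econ.C_c * float(cons_per_hh.sum())
    pop.money += econ.P_p * prod_per_hh - econ.C_c * cons_per_hh

    new_p = int(pop.is_producer[new_idx].sum()) if len(new_idx) else 0
    cum_p += new_p
    cum_c += len(new_idx) - new_p
    record = AbmDayRecord(
        day=day,
        **_census(pop),
        cumulative_infections_p=cum_p,
        cumulative_infections_c=cum_c,
        n_bankrupt_households=int((pop.money <= 0.0).sum()),
        total_money=float(pop.money.sum()),
        production=production,
        consumption=consumption,
        treatment_spend=treatment_spend,
        new_infections=len(new_idx),
        new_treated=n_treated,
        hatted_draws=hatted_draws,
    )
    return record, cum_p, cum_c


def advance_day(
    pop: HouseholdPopulation,
    params: ModelParams,
    policy: TreatmentPolicy,
    rng: np.random.Generator,
    day: int = 0,
    cumulative_p: int = 0,
    cumulative_c: int = 0,
) -> tuple[HouseholdPopulation, AbmDayRecord]:
    """Apply one day's updates to a copy of the population."""
    out = pop.copy()
    record, _, _ = _advance_day_inplace(
        out, params, policy, rng, day, cumulative_p, cumulative_c
    )
    return out, record


def run_abm(
    params: ModelParams,
    demog: Demography,
    policy: TreatmentPolicy,
    seed: int | np.random.SeedSequence,
    max_days: int = 1000,
    keep_population: bool = False,
) -> AbmResult:
    """Simulate one outbreak from a single untreated producer index case.

    Iterates daily updates until no infectives remain or ``max_days`` is
    reached (the result is then flagged ``truncated``).
    """
    if max_days < 1:
        raise ValueError("max_days must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    pop_seed, case_seed, day_seed = ss.spawn(3)
    pop = synthesize_population(demog, params.econ.M0, pop_seed)
    pop = seed_index_case(pop, case_seed)
    rng = np.random.default_rng(day_seed)

    trajectory: list[AbmDayRecord] = []
    cum_p, cum_c = 1, 0  # the index case
    truncated = False
    day = 0
    while True:
        day += 1
        record, cum_p, cum_c = _advance_day_inplace(
            pop, params, policy, rng, day, cum_p, cum_c
        )
        trajectory.append(record)
        no_infectives = (
            record.i_untreated_p + record.i_treated_p
            + record.i_untreated_c + record.i_treated_c
        ) == 0
        if no_infectives:
            break
        if day >= max_days:
            truncated = True
            break
    return AbmResult(
        trajectory=trajectory,
        final_burden_p=cum_p,
        final_burden_c=cum_c,
        seed=ss.entropy if isinstance(ss.entropy, int) else None,
        truncated=truncated,
        population=pop if keep_population else None,
    )


def monte_carlo_burden(
    params: ModelParams,
    demog: Demography,
    policy: TreatmentPolicy,
    n_reps: int,
    seed: int | np.random.SeedSequence,
    max_days: int = 1000,
) -> MonteCarloSummary:
    """Mean and standard error of (producer, consumer) burden over replicates.

    Replicates use disjoint child seed streams spawned from ``seed``.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 to estimate a standard error")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_reps)
    keys = {tuple(c.generate_state(4)) for c in children}
    if len(keys) != n_reps:
        raise ValueError("replicate seed streams are not distinct")
    bp = np.empty(n_reps)
    bc = np.empty(n_reps)
    for k, child in enumerate(children):
        res = run_abm(params, demog, policy, child, max_days=max_days)
        bp[k] = res.final_burden_p
        bc[k] = res.final_burden_c
    return MonteCarloSummary(
        mean_burden_p=float(bp.mean()),
        mean_burden_c=float(bc.mean()),
        se_burden_p=float(bp.std(ddof=1) / np.sqrt(n_reps)),
        se_burden_c=float(bc.std(ddof=1) / np.sqrt(n_reps)),
        burdens_p=bp,
        burdens_c=bc,
        n_reps=n_reps,
    )
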