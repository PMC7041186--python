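"""Shared independent oracles used by unit and acceptance tests.

Everything here is deliberately written from the model definitions directly
(hand-expanded expressions, explicit enumeration), independent of the package
implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from housepi import (
    Demography,
    ModelParams,
    TreatmentPolicy,
)
from housepi.population import I_TREATED, I_UNTREATED, R, S, HouseholdPopulation


def reference_rhs(y, params: ModelParams, policy: TreatmentPolicy, h_size=5.0, n=2500.0):
    """Hand-expanded right-hand side of the switched system (oracle).

    Written term by term from the model's printed form, without the A/B
    shorthand factoring used by the implementation.
    """
    e = params.ode_rates()
    s_p, i_p, i_pp, r_p, s_c, i_c, i_cp, r_c, m = y
    it_p = h_size / n * (i_p + i_pp)
    it_c = h_size / n * (i_c + i_cp)
    bankrupt = m <= 0.0
    if not bankrupt:
        inc_p = (
            e.beta_p * s_p * (i_p + i_pp) / n
            + e.beta_p * s_p * (i_c + i_cp) / n
            + e.iota_p * s_p * it_p
            + e.iota_p * s_p * it_c
        )
        inc_c = (
            e.beta_c * s_c * (i_p + i_pp) / n
            + e.beta_c * s_c * (i_c + i_cp) / n
            + e.iota_c * s_c * it_p
            + e.iota_c * s_c * it_c
        )
        d = [
            -inc_p,
            inc_p * (1 - policy.T_p) - e.gamma_p * i_p,
            inc_p * policy.T_p - e.gamma_plus_p * i_pp,
            e.gamma_p * i_p + e.gamma_plus_p * i_pp,
            -inc_c,
            inc_c * (1 - policy.T_c) - e.gamma_c * i_c,
            inc_c * policy.T_c - e.gamma_plus_c * i_cp,
            e.gamma_c * i_c + e.gamma_plus_c * i_cp,
        ]
    else:
        inc_p = (
            e.beta_hat_p * s_p * (i_p + i_pp) / n
            + e.beta_hat_p * s_p * (i_c + i_cp) / n
            + e.iota_hat_p * s_p * it_p
            + e.iota_hat_p * s_p * it_c
        )
        inc_c = (
            e.beta_hat_c * s_c * (i_p + i_pp) / n
            + e.beta_hat_c * s_c * (i_c + i_cp) / n
            + e.iota_hat_c * s_c * it_p
            + e.iota_hat_c * s_c * it_c
        )
        d = [
            -inc_p,
            inc_p - e.gamma_p * i_p,
            -e.gamma_p * i_pp,
            e.gamma_p * (i_p + i_pp),
            -inc_c,
            inc_c - e.gamma_c * i_c,
            -e.gamma_c * i_cp,
            e.gamma_c * (i_c + i_cp),
        ]
    econ = params.econ
    flows = (
        econ.P_p * (s_p + i_pp + r_p)
        - econ.C_c * (s_c + i_c + i_cp + i_p + r_c)
        - econ.C_t * (i_pp + i_cp)
    )
    divisor = n / h_size if params.money_scale == "per_household" else n
    d.append(flows / divisor)
    return np.array(d)


def two_household_test_population() -> HouseholdPopulation:
    """Fixed 5-individual, 2-household state used by the enumeration oracle.

    Household 0 (solvent, money 500): producer infected-untreated, consumer S.
    Household 1 (bankrupt, money -5): producer S, consumer S, consumer
    infected-treated.
    """
    return HouseholdPopulation(
        household_of=np.array([0, 0, 1, 1, 1], dtype=np.int32),
        is_producer=np.array([True, False, True, False, False]),
        state=np.array([I_UNTREATED, S, S, S, I_TREATED], dtype=np.int8),
        money=np.array([500.0, -5.0]),
    )


def enumerate_one_day_marginals(
    params: ModelParams, policy: TreatmentPolicy
) -> dict[int, dict[int, float]]:
    """Exact per-individual end-of-day state distribution for the fixed state.

    Individuals evolve independently within one day given the start-of-day
    exposure snapshot (recovery draws, composite infection draws, coverage
    draws), except for treatment affordability, which binds only through the
    household purse; in this state household 0 can afford any single
    treatment and household 1 (bankrupt) can afford none, so marginals
    factorise exactly.
    """
    e = params.epi
    n = 5
    # start-of-day exposure: infectives are individuals 0 (hh0) and 4 (hh1)
    # individual 1: solvent consumer, 1 outside infective, 1 in household
    p1 = 1 - (1 - e.beta_c / (n - 1)) ** 1 * (1 - e.iota_c) ** 1
    # individual 2: bankrupt producer, 1 outside, 1 in household
    p2 = 1 - (1 - e.beta_hat_p / (n - 1)) ** 1 * (1 - e.iota_hat_p) ** 1
    # individual 3: bankrupt consumer, same exposure as 2
    p3 = 1 - (1 - e.beta_hat_c / (n - 1)) ** 1 * (1 - e.iota_hat_c) ** 1
    return {
        0: {I_UNTREATED: 1 - e.gamma_p, R: e.gamma_p},
        1: {
            S: 1 - p1,
            I_TREATED: p1 * policy.T_c,  # household 0 is solvent
            I_UNTREATED: p1 * (1 - policy.T_c),
        },
        2: {S: 1 - p2, I_UNTREATED: p2},  # bankrupt: never treated
        3: {S: 1 - p3, I_UNTREATED: p3},
        4: {I_TREATED: 1 - e.gamma_plus_c, R: e.gamma_plus_c},
    }
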