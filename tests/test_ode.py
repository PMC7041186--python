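import numpy as np
import pytest
from scipy.integrate import solve_ivp

from housepi import (
    Demography,
    EconParams,
    EpiParams,
    HouseholdScaling,
    ModelParams,
    OdeState,
    TreatmentPolicy,
    consumer_burden,
    force_terms,
    ode_rhs,
    run_ode,
    run_ode_euler,
)
from housepi.abm import _advance_day_inplace
from housepi.population import I_UNTREATED, synthesize_population

from helpers import reference_rhs


def _random_states(rng, n=10):
    for _ in range(n):
        y = rng.uniform(0, 400, size=9)
        y[8] = rng.uniform(-200, 200)
        yield y


class TestForceTerms:
    def test_zero_without_infectives(self):
        state = OdeState(S_p=1000, I_p=0, S_c=1500)
        assert force_terms(state, EpiParams(), HouseholdScaling()) == (0, 0, 0, 0)

    def test_hatted_forces_at_least_as_strong(self, rng):
        epi = EpiParams()
        scaling = HouseholdScaling()
        for y in _random_states(rng):
            state = OdeState.from_array(np.abs(y))
            a, b, a_hat, b_hat = force_terms(state, epi, scaling)
            assert a <= 0 and b <= 0
            assert a_hat <= a and b_hat <= b

    def test_spot_state_matches_hand_coded_expressions(self):
        """S_p=999, I_p=1 spot check against independently expanded terms."""
        state = OdeState(S_p=999, I_p=1, S_c=0, M_h=1.0)
        a, b, a_hat, b_hat = force_terms(state, EpiParams(), HouseholdScaling())
        expected_a = -(0.3 * 999 * 1 / 2500 + 0.03 * 999 * (5 / 2500))
        assert a == pytest.approx(expected_a, abs=1e-12)
        assert b == 0.0
        expected_a_hat = -(0.4 * 999 * 1 / 2500 + 0.04 * 999 * (5 / 2500))
        assert a_hat == pytest.approx(expected_a_hat, abs=1e-12)


class TestRhs:
    @pytest.mark.parametrize("money_scale", ["per_household", "per_capita"])
    def test_matches_independent_reference(self, rng, money_scale):
        params = ModelParams(
            econ=EconParams(C_c=30.0, C_t=250.0), money_scale=money_scale
        )
        policy = TreatmentPolicy(0.51, 0.51)
        scaling = HouseholdScaling()
        for y in _random_states(rng):
            state = OdeState.from_array(np.concatenate([np.abs(y[:8]), [y[8]]]))
            got = ode_rhs(state, params, policy, scaling)
            want = reference_rhs(state.to_array(), params, policy)
            assert np.allclose(got, want, atol=1e-12)

    def test_no_infectives_solvent(self):
        state = OdeState(S_p=1000, I_p=0, S_c=1500, M_h=500)
        params = ModelParams(econ=EconParams(C_c=30.0, C_t=250.0))
        d = ode_rhs(state, params, TreatmentPolicy(0.5, 0.5), HouseholdScaling())
        assert np.allclose(d[:8], 0.0)
        assert d[8] == pytest.approx((50.0 * 1000 - 30.0 * 1500) / 500.0)

    def test_role_totals_conserved_in_both_branches(self, rng):
        params = ModelParams(econ=EconParams(C_c=30.0, C_t=250.0))
        policy = TreatmentPolicy(0.3, 0.8)
        scaling = HouseholdScaling()
        for y in _random_states(rng):
            state = OdeState.from_array(np.concatenate([np.abs(y[:8]), [y[8]]]))
            for bankrupt in (False, True):
                d = ode_rhs(state, params, policy, scaling, bankrupt=bankrupt)
                assert d[:4].sum() == pytest.approx(0.0, abs=1e-10)
                assert d[4:8].sum() == pytest.approx(0.0, abs=1e-10)


class TestRunOde:
    def test_no_transmission_burdens_are_index_case_only(self):
        epi = EpiParams(
            beta_p=0, beta_c=0, beta_hat_p=0, beta_hat_c=0,
            iota_p=0, iota_c=0, iota_hat_p=0, iota_hat_c=0,
        )
        params = ModelParams(epi=epi, econ=EconParams(C_c=30.0, C_t=250.0))
        traj = run_ode(params, TreatmentPolicy(0.5, 0.5))
        assert traj.burden_p == pytest.approx(1.0, abs=1e-6)
        assert traj.burden_c == pytest.approx(0.0, abs=1e-6)
        assert np.all(np.diff(traj.states[:, 4]) <= 1e-12)  # S_c never decreases

    def test_conservation_and_nonnegativity_along_trajectory(self, default_params):
        traj = run_ode(default_params, TreatmentPolicy(0.51, 0.51))
        prod = traj.states[:, :4].sum(axis=1)
        cons = traj.states[:, 4:8].sum(axis=1)
        assert np.allclose(prod, 1000.0, atol=1e-6)
        assert np.allclose(cons, 1500.0, atol=1e-6)
        assert traj.states[:, :8].min() >= -1e-9

    def test_bankruptcy_intervals_consistent_with_money_sign(self, default_params):
        traj = run_ode(default_params, TreatmentPolicy(0.51, 0.51))
        assert len(traj.bankruptcy_intervals) >= 1
        starts = [a for a, _ in traj.bankruptcy_intervals]
        ends = [b for _, b in traj.bankruptcy_intervals]
        assert all(a < b for a, b in traj.bankruptcy_intervals)
        assert starts == sorted(starts)
        # interiors of intervals have non-positive money, exteriors positive
        mid_mask = traj.branch.astype(bool)
        assert np.all(traj.states[mid_mask, 8] <= 1e-9)
        interior = (~mid_mask) & (traj.times > 0)
        assert np.all(traj.states[interior, 8] >= -1e-9)
        # crossing located sharply: money at interval starts is ~0
        for a in starts:
            k = np.searchsorted(traj.times, a)
            assert abs(traj.states[k, 8]) < 1e-6 * 500.0

    def test_worked_example_matches_independent_event_located_integration(
        self, default_params
    ):
        """Frozen oracle: SciPy LSODA with terminal-event switching gives
        consumer burden 1499.53 at equal coverage 0.51 (C_c=30, C_t=250)."""
        traj = run_ode(default_params, TreatmentPolicy(0.51, 0.51))
        assert traj.burden_c == pytest.approx(1499.53, abs=0.1)
        assert traj.bankruptcy_intervals[0] == pytest.approx((20.81, 214.47), abs=0.05)

    def test_tolerance_halving_stability(self, default_params):
        a = run_ode(default_params, TreatmentPolicy(0.51, 0.51), rtol=1e-8, atol=1e-10)
        b = run_ode(default_params, TreatmentPolicy(0.51, 0.51), rtol=5e-9, atol=5e-11)
        assert abs(a.burden_c - b.burden_c) / b.burden_c < 1e-4
        assert abs(a.burden_p - b.burden_p) / b.burden_p < 1e-4

    def test_euler_day_grid_cross_check(self, default_params):
        """The independent fixed-step integrator lands within ~1% on burdens."""
        fine = run_ode(default_params, TreatmentPolicy(0.51, 0.51))
        euler = run_ode_euler(default_params, TreatmentPolicy(0.51, 0.51), dt=0.5)
        assert euler.burden_c == pytest.approx(fine.burden_c, rel=0.01)
        assert euler.burden_p == pytest.approx(fine.burden_p, rel=0.01)
        assert len(euler.bankruptcy_intervals) == len(fine.bankruptcy_intervals)

    def test_scipy_cross_check_solvent_dynamics(self):
        """Against scipy.solve_ivp on a configuration that never goes bankrupt."""
        params = ModelParams(econ=EconParams(C_c=0.0, C_t=0.0))
        policy = TreatmentPolicy(0.4, 0.6)
        traj = run_ode(params, policy, rtol=1e-10, atol=1e-12)

        def rhs(t, y):
            return ode_rhs(OdeState.from_array(y), params, policy, HouseholdScaling())

        sol = solve_ivp(
            rhs, (0, traj.times[-1]), OdeState(M_h=500).to_array(),
            method="LSODA", rtol=1e-10, atol=1e-12,
        )
        assert sol.y[0, -1] == pytest.approx(traj.states[-1, 0], rel=1e-5, abs=1e-5)
        assert sol.y[4, -1] == pytest.approx(traj.states[-1, 4], rel=1e-5, abs=1e-5)

    def test_economics_off_burden_invariant_to_economy(self, economics_off_params):
        """With hats collapsed and gamma+ = gamma the system is a plain
        two-group SIR: burdens ignore C_c, C_t, T_p, T_c to < 1e-8."""
        rng = np.random.default_rng(6)
        ref = None
        for _ in range(5):
            econ = EconParams(
                C_c=float(rng.uniform(0, 50)),
                C_t=float(rng.uniform(0, 500)),
                M0=float(rng.uniform(1, 1000)),
            )
            params = ModelParams(epi=economics_off_params.epi, econ=econ)
            policy = TreatmentPolicy(float(rng.uniform(0, 1)), float(rng.uniform(0, 1)))
            traj = run_ode(params, policy, rtol=1e-10, atol=1e-12)
            if ref is None:
                ref = (traj.burden_p, traj.burden_c)
            else:
                assert traj.burden_p == pytest.approx(ref[0], abs=1e-8 * 1000)
                assert traj.burden_c == pytest.approx(ref[1], abs=1e-8 * 1500)

    def test_truncated_trajectory_flagged_by_burden_readers(self, default_params):
        traj = run_ode(default_params, TreatmentPolicy(0.51, 0.51), t_max=5.0)
        assert traj.truncated
        with pytest.raises(ValueError):
            consumer_burden(traj)


class TestAbmOdeCrossCheck:
    def test_well_mixed_economics_off_agreement(self):
        """Stochastic and mean-field engines agree when both are well-mixed.

        Households' within-home term is switched off (the mean-field form
        never saturates, the agent model's does, so they are only directly
        comparable in the global-mixing limit) and both engines start from
        the same 25 infected producers to suppress extinction bimodality.
        """
        epi = EpiParams(
            beta_hat_p=0.3, beta_hat_c=0.5,
            iota_p=0, iota_c=0, iota_hat_p=0, iota_hat_c=0,
        )
        params = ModelParams(epi=epi, econ=EconParams(C_c=0.0, C_t=0.0))
        demog = Demography()
        policy = TreatmentPolicy(0.5, 0.5)
        traj = run_ode(params, policy, init=OdeState(S_p=975, I_p=25, S_c=1500, M_h=500))

        n_reps = 60
        burdens_p = np.empty(n_reps)
        burdens_c = np.empty(n_reps)
        ss = np.random.SeedSequence(777)
        for k, child in enumerate(ss.spawn(n_reps)):
            pop_seed, run_seed = child.spawn(2)
            pop = synthesize_population(demog, 500.0, pop_seed)
            gen = np.random.default_rng(run_seed)
            idx = gen.choice(np.flatnonzero(pop.is_producer), size=25, replace=False)
            pop.state[idx] = I_UNTREATED
            cum_p, cum_c = 25, 0
            day = 0
            while True:
                day += 1
                rec, cum_p, cum_c = _advance_day_inplace(
                    pop, params, policy, gen, day, cum_p, cum_c
                )
                if (
                    rec.i_untreated_p + rec.i_treated_p
                    + rec.i_untreated_c + rec.i_treated_c
                ) == 0 or day > 800:
                    break
            burdens_p[k] = cum_p
            burdens_c[k] = cum_c
        se_p = burdens_p.std(ddof=1) / np.sqrt(n_reps)
        se_c = burdens_c.std(ddof=1) / np.sqrt(n_reps)
        assert abs(burdens_p.mean() - traj.burden_p) <= 3 * se_p
        assert abs(burdens_c.mean() - traj.burden_c) <= 3 * se_c
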