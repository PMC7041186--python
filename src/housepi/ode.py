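"""Continuous regime-switching ODE twin of the household epidemic model.

State vector (9 components): ``[S_p, I_p, I_p+, R_p, S_c, I_c, I_c+, R_c, M_h]``
where ``+`` marks treated infectives and ``M_h`` is the collective money
variable.  While solvent (``M_h > 0``) new cases are split between the
treated and untreated compartments by the coverage fractions ``T_p, T_c``;
once bankrupt (``M_h <= 0``) transmission takes its elevated (hatted) values,
no new case is treated, and already-treated individuals lose the enhanced
recovery rate (they recover at the baseline ``gamma``).

The force-of-infection terms combine frequency-dependent global mixing
``beta S I / N`` with within-household pressure ``iota S I~`` expressed
through the household-weighted prevalences ``I~ = (|h|/N)(I + I+)``.

Money flows follow ``P_p (S_p + I_p+ + R_p) - C_c (S_c + I_c + I_c+ + I_p
+ R_c) - C_t (I_p+ + I_c+)`` divided by the number of households
(``money_scale="per_household"``, the default, keeping ``M_h`` in the same
per-household units as its initial value ``M0 = 500``) or by the population
size (``money_scale="per_capita"``).

The default integrator is an adaptive Dormand-Prince 5(4) scheme compiled
with numba, with the ``M_h = 0`` crossing located on the dense (cubic
Hermite) output to 1e-9 day and the branch switched exactly there; a
fixed-step day-grid Euler integrator is provided as an independent
cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import Demography, EpiParams, ModelParams, TreatmentPolicy

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


__all__ = [
    "OdeState",
    "HouseholdScaling",
    "OdeTrajectory",
    "force_terms",
    "ode_rhs",
    "run_ode",
    "run_ode_euler",
    "consumer_burden",
    "producer_burden",
    "default_initial_state",
]

INFECTIVE_EXTINCTION = 1e-6  # total infectives below this ends the epidemic


@dataclass(frozen=True)
class HouseholdScaling:
    """Average household size and total population for the mean-field model."""

    h_size: float = 5.0
    n_population: float = 2500.0

    def __post_init__(self) -> None:
        if self.h_size <= 0 or self.n_population <= 0:
            raise ValueError("household size and population must be positive")

    @property
    def n_households(self) -> float:
        return self.n_population / self.h_size

    @classmethod
    def from_demography(cls, demog: Demography) -> "HouseholdScaling":
        return cls(
            h_size=demog.mean_household_size,
            n_population=demog.population_size,
        )


@dataclass(frozen=True)
class OdeState:
    """Continuous compartment counts plus the collective money variable."""

    S_p: float = 999.0
    I_p: float = 1.0
    I_p_plus: float = 0.0
    R_p: float = 0.0
    S_c: float = 1500.0
    I_c: float = 0.0
    I_c_plus: float = 0.0
    R_c: float = 0.0
    M_h: float = 500.0

    def __post_init__(self) -> None:
        for name in ("S_p", "I_p", "I_p_plus", "R_p", "S_c", "I_c", "I_c_plus", "R_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"compartment {name} must be non-negative")

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.S_p, self.I_p, self.I_p_plus, self.R_p,
             self.S_c, self.I_c, self.I_c_plus, self.R_c, self.M_h]
        )

    @classmethod
    def from_array(cls, y: np.ndarray) -> "OdeState":
        return cls(*map(float, y))

    @property
    def total_producers(self) -> float:
        return self.S_p + self.I_p + self.I_p_plus + self.R_p

    @property
    def total_consumers(self) -> float:
        return self.S_c + self.I_c + self.I_c_plus + self.R_c

    @property
    def total_infectives(self) -> float:
        return self.I_p + self.I_p_plus + self.I_c + self.I_c_plus


def default_initial_state(m0: float = 500.0) -> OdeState:
    """One untreated infected producer in an otherwise susceptible population."""
    return OdeState(S_p=999.0, I_p=1.0, S_c=1500.0, M_h=m0)


@dataclass
class OdeTrajectory:
    times: np.ndarray
    states: np.ndarray  # shape (n_times, 9)
    branch: np.ndarray  # int8, 0 = solvent, 1 = bankrupt (branch used leaving t)
    bankruptcy_intervals: list[tuple[float, float]]
    burden_p: float
    burden_c: float
    truncated: bool = False

    @property
    def final_state(self) -> OdeState:
        return OdeState.from_array(self.states[-1])

    def to_frame(self) -> pd.DataFrame:
        cols = ["S_p", "I_p", "I_p_plus", "R_p", "S_c", "I_c", "I_c_plus", "R_c", "M_h"]
        frame = pd.DataFrame(self.states, columns=cols)
        frame.insert(0, "t", self.times)
        frame["bankrupt"] = self.branch.astype(int)
        return frame


def force_terms(
    state: OdeState, params: EpiParams, scaling: HouseholdScaling
) -> tuple[float, float, float, float]:
    """The four (signed, non-positive) force-of-infection expressions.

    Returns ``(A, B, A_hat, B_hat)``: the solvent and bankrupt forces acting
    on susceptible producers (A) and consumers (B).  Each is the negative of
    the corresponding incidence rate; all four vanish when no infectives
    are present.
    """
    n = scaling.n_population
    i_p = state.I_p + state.I_p_plus
    i_c = state.I_c + state.I_c_plus
    it_p = scaling.h_size / n * i_p
    it_c = scaling.h_size / n * i_c

    def force(beta: float, iota: float, s: float) -> float:
        return -(beta * s * i_p / n + beta * s * i_c / n + iota * s * it_p + iota * s * it_c)

    return (
        force(params.beta_p, params.iota_p, state.S_p),
        force(params.beta_c, params.iota_c, state.S_c),
        force(params.beta_hat_p, params.iota_hat_p, state.S_p),
        force(params.beta_hat_c, params.iota_hat_c, state.S_c),
    )


def ode_rhs(
    state: OdeState,
    params: ModelParams,
    policy: TreatmentPolicy,
    scaling: HouseholdScaling,
    bankrupt: bool | None = None,
) -> np.ndarray:
    """Time derivative of the 9-component state on the active branch.

    The branch defaults to the sign of ``M_h`` (bankrupt iff ``M_h <= 0``)
    but can be forced for testing.  Reference implementation in plain
    Python; the compiled integrator core reproduces it (asserted in the
    test-suite) and is used for time stepping.
    """
    epi = params.ode_rates()
    econ = params.econ
    if bankrupt is None:
        bankrupt = state.M_h <= 0.0
    a, b, a_hat, b_hat = force_terms(state, epi, scaling)
    if not bankrupt:
        d_s_p = a
        d_i_p = -a * (1.0 - policy.T_p) - epi.gamma_p * state.I_p
        d_i_p_plus = -a * policy.T_p - epi.gamma_plus_p * state.I_p_plus
        d_r_p = epi.gamma_p * state.I_p + epi.gamma_plus_p * state.I_p_plus
        d_s_c = b
        d_i_c = -b * (1.0 - policy.T_c) - epi.gamma_c * state.I_c
        d_i_c_plus = -b * policy.T_c - epi.gamma_plus_c * state.I_c_plus
        d_r_c = epi.gamma_c * state.I_c + epi.gamma_plus_c * state.I_c_plus
    else:
        # all new cases untreated; treated individuals fall back to gamma
        d_s_p = a_hat
        d_i_p = -a_hat - epi.gamma_p * state.I_p
        d_i_p_plus = -epi.gamma_p * state.I_p_plus
        d_r_p = epi.gamma_p * (state.I_p + state.I_p_plus)
        d_s_c = b_hat
        d_i_c = -b_hat - epi.gamma_c * state.I_c
        d_i_c_plus = -epi.gamma_c * state.I_c_plus
        d_r_c = epi.gamma_c * (state.I_c + state.I_c_plus)
    flows = (
        econ.P_p * (state.S_p + state.I_p_plus + state.R_p)
        - econ.C_c * (state.S_c + state.I_c + state.I_c_plus + state.I_p + state.R_c)
        - econ.C_t * (state.I_p_plus + state.I_c_plus)
    )
    divisor = (
        scaling.n_households
        if params.money_scale == "per_household"
        else scaling.n_population
    )
    d_m = flows / divisor
    return np.array(
        [d_s_p, d_i_p, d_i_p_plus, d_r_p, d_s_c, d_i_c, d_i_c_plus, d_r_c, d_m]
    )


# --------------------------------------------------------------------------
# compiled Dormand-Prince 5(4) core with event-located branch switching
# --------------------------------------------------------------------------

# Butcher tableau (Dormand & Prince 1980); row 7 doubles as the 5th-order
# solution weights (FSAL).
_DP_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_DP_A = np.array(
    [
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [1 / 5, 0.0, 0.0, 0.0, 0.0, 0.0],
        [3 / 40, 9 / 40, 0.0, 0.0, 0.0, 0.0],
        [44 / 45, -56 / 15, 32 / 9, 0.0, 0.0, 0.0],
        [19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729, 0.0, 0.0],
        [9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656, 0.0],
        [35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84],
    ]
)
_DP_B5 = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0.0])
_DP_B4 = np.array(
    [5179 / 57600, 0.0, 7571 / 16695, 393 / 640, -92097 / 339200, 187 / 2100, 1 / 40]
)

_SWITCH_DWELL = 1e-6  # commit to a branch for at least this long after a switch
_CROSSING_TOL = 1e-9  # located crossing-time resolution (days)


@njit(cache=True)
def _rhs_nb(y, p, bankrupt, out):
    # p layout: [beta_p, beta_c, beta_hat_p, beta_hat_c,
    #            iota_p, iota_c, iota_hat_p, iota_hat_c,
    #            gamma_p, gamma_c, gamma_plus_p, gamma_plus_c,
    #            P_p, C_c, C_t, T_p, T_c, h_size, N, money_divisor]
    n = p[18]
    i_p = y[1] + y[2]
    i_c = y[5] + y[6]
    it_p = p[17] / n * i_p
    it_c = p[17] / n * i_c
    if bankrupt == 0:
        a = -(p[0] * y[0] * i_p / n + p[0] * y[0] * i_c / n
              + p[4] * y[0] * it_p + p[4] * y[0] * it_c)
        b = -(p[1] * y[4] * i_p / n + p[1] * y[4] * i_c / n
              + p[5] * y[4] * it_p + p[5] * y[4] * it_c)
        out[0] = a
        out[1] = -a * (1.0 - p[15]) - p[8] * y[1]
        out[2] = -a * p[15] - p[10] * y[2]
        out[3] = p[8] * y[1] + p[10] * y[2]
        out[4] = b
        out[5] = -b * (1.0 - p[16]) - p[9] * y[5]
        out[6] = -b * p[16] - p[11] * y[6]
        out[7] = p[9] * y[5] + p[11] * y[6]
    else:
        a = -(p[2] * y[0] * i_p / n + p[2] * y[0] * i_c / n
              + p[6] * y[0] * it_p + p[6] * y[0] * it_c)
        b = -(p[3] * y[4] * i_p / n + p[3] * y[4] * i_c / n
              + p[7] * y[4] * it_p + p[7] * y[4] * it_c)
        out[0] = a
        out[1] = -a - p[8] * y[1]
        out[2] = -p[8] * y[2]
        out[3] = p[8] * (y[1] + y[2])
        out[4] = b
        out[5] = -b - p[9] * y[5]
        out[6] = -p[9] * y[6]
        out[7] = p[9] * (y[5] + y[6])
    flows = (p[12] * (y[0] + y[2] + y[3])
             - p[13] * (y[4] + y[5] + y[6] + y[1] + y[7])
             - p[14] * (y[2] + y[6]))
    out[8] = flows / p[19]


@njit(cache=True)
def _hermite(y0, f0, y1, f1, dt, theta, out):
    t2 = theta * theta
    t3 = t2 * theta
    h00 = 2.0 * t3 - 3.0 * t2 + 1.0
    h10 = t3 - 2.0 * t2 + theta
    h01 = -2.0 * t3 + 3.0 * t2
    h11 = t3 - t2
    for i in range(y0.shape[0]):
        out[i] = h00 * y0[i] + h10 * dt * f0[i] + h01 * y1[i] + h11 * dt * f1[i]


@njit(cache=True)
def _dp45_switched(y0, p, t_max, rtol, atol, max_steps):
    """Adaptive DP5(4) with money-sign branch switching and extinction stop.

    Returns (ts, ys, branches, n_points, status) where status is
    0 = infectives extinct, 1 = reached t_max, 2 = step-count exceeded,
    3 = step size collapsed.
    """
    ndim = y0.shape[0]
    ts = np.empty(max_steps + 1)
    ys = np.empty((max_steps + 1, ndim))
    brs = np.empty(max_steps + 1, dtype=np.int8)

    t = 0.0
    y = y0.copy()
    bankrupt = 1 if y[8] <= 0.0 else 0
    ts[0] = t
    ys[0] = y
    brs[0] = bankrupt
    n_pts = 1

    k = np.empty((7, ndim))
    ytmp = np.empty(ndim)
    yint = np.empty(ndim)
    y5 = np.empty(ndim)
    f_new = np.empty(ndim)
    _rhs_nb(y, p, bankrupt, k[0])

    dt = 1e-2
    last_switch = -1.0
    status = 1
    while t < t_max and n_pts <= max_steps:
        if dt < 1e-13:
            status = 3
            break
        if t + dt > t_max:
            dt = t_max - t
        # stages (k[0] holds f(t, y))
        for s in range(1, 7):
            for i in range(ndim):
                acc = 0.0
                for j in range(s):
                    acc += _DP_A[s, j] * k[j][i]
                ytmp[i] = y[i] + dt * acc
            _rhs_nb(ytmp, p, bankrupt, k[s])
        for i in range(ndim):
            acc5 = 0.0
            acc4 = 0.0
            for s in range(7):
                acc5 += _DP_B5[s] * k[s][i]
                acc4 += _DP_B4[s] * k[s][i]
            y5[i] = y[i] + dt * acc5
            ytmp[i] = acc5 - acc4  # reuse as error vector / dt
        # error norm
        err = 0.0
        for i in range(ndim):
            sc = atol + rtol * max(abs(y[i]), abs(y5[i]))
            e = dt * ytmp[i] / sc
            err += e * e
        err = np.sqrt(err / ndim)
        if err > 1.0:
            dt *= max(0.2, 0.9 * err ** -0.2)
            continue

        # accepted; FSAL derivative at the step end
        _rhs_nb(y5, p, bankrupt, f_new)

        crossed = False
        theta_cross = 1.0
        if bankrupt == 0:
            if y5[8] <= 0.0:
                crossed = True
        else:
            if y5[8] > 0.0:
                crossed = True
        if crossed and t + dt > last_switch + _SWITCH_DWELL:
            # bisect the money component of the Hermite interpolant
            lo = 0.0
            hi = 1.0
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                _hermite(y, k[0], y5, f_new, dt, mid, yint)
                pos = yint[8] > 0.0
                if (bankrupt == 0 and pos) or (bankrupt == 1 and not pos):
                    lo = mid
                else:
                    hi = mid
                if (hi - lo) * dt < _CROSSING_TOL:
                    break
            theta_cross = hi
            _hermite(y, k[0], y5, f_new, dt, theta_cross, yint)
            t = t + theta_cross * dt
            for i in range(ndim):
                y[i] = yint[i]
            y[8] = 0.0 if bankrupt == 0 else y[8]
            bankrupt = 1 - bankrupt
            last_switch = t
            ts[n_pts] = t
            ys[n_pts] = y
            brs[n_pts] = bankrupt
            n_pts += 1
            _rhs_nb(y, p, bankrupt, k[0])
            dt = max(dt * 0.5, 1e-6)
            continue

        t += dt
        for i in range(ndim):
            y[i] = y5[i]
            k[0][i] = f_new[i]
        ts[n_pts] = t
        ys[n_pts] = y
        brs[n_pts] = bankrupt
        n_pts += 1
        if y[1] + y[2] + y[5] + y[6] < INFECTIVE_EXTINCTION:
            status = 0
            break
        if err > 1e-30:
            dt *= min(5.0, 0.9 * err ** -0.2)
        else:
            dt *= 5.0
    else:
        if n_pts > max_steps:
            status = 2
    return ts[:n_pts], ys[:n_pts], brs[:n_pts], n_pts, status


def _pack_params(
    params: ModelParams, policy: TreatmentPolicy, scaling: HouseholdScaling
) -> np.ndarray:
    epi = params.ode_rates()
    econ = params.econ
    divisor = (
        scaling.n_households
        if params.money_scale == "per_household"
        else scaling.n_population
    )
    return np.array(
        [
            epi.beta_p, epi.beta_c, epi.beta_hat_p, epi.beta_hat_c,
            epi.iota_p, epi.iota_c, epi.iota_hat_p, epi.iota_hat_c,
            epi.gamma_p, epi.gamma_c, epi.gamma_plus_p, epi.gamma_plus_c,
            econ.P_p, econ.C_c, econ.C_t, policy.T_p, policy.T_c,
            scaling.h_size, scaling.n_population, divisor,
        ]
    )


def _bankruptcy_intervals(
    times: np.ndarray, branch: np.ndarray
) -> list[tuple[float, float]]:
    intervals: list[tuple[float, float]] = []
    start = times[0] if branch[0] else None
    for k in range(1, len(times)):
        if branch[k] and not branch[k - 1]:
            start = times[k]
        elif not branch[k] and branch[k - 1] and start is not None:
            intervals.append((float(start), float(times[k])))
            start = None
    if start is not None:
        intervals.append((float(start), float(times[-1])))
    return intervals


def run_ode(
    params: ModelParams,
    policy: TreatmentPolicy,
    scaling: HouseholdScaling | None = None,
    init: OdeState | None = None,
    t_max: float = 3000.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_steps: int = 200_000,
) -> OdeTrajectory:
    """Integrate the switched system until extinction or ``t_max``.

    Burdens are cumulative infections per role: the initial role total
    (including any index cases) minus the final susceptibles.  A trajectory
    that reaches ``t_max`` with infectives remaining is flagged truncated.
    """
    scaling = scaling or HouseholdScaling()
    init = init or default_initial_state(params.econ.M0)
    p = _pack_params(params, policy, scaling)
    y0 = init.to_array()
    ts, ys, brs, n_pts, status = _dp45_switched(y0, p, t_max, rtol, atol, max_steps)
    if status == 3:
        raise RuntimeError(f"integrator step size collapsed at t = {ts[-1]:.6f}")
    if status == 2:
        raise RuntimeError(f"step budget exhausted at t = {ts[-1]:.6f}")
    return OdeTrajectory(
        times=ts,
        states=ys,
        branch=brs,
        bankruptcy_intervals=_bankruptcy_intervals(ts, brs),
        burden_p=float(init.total_producers - ys[-1, 0]),
        burden_c=float(init.total_consumers - ys[-1, 4]),
        truncated=(status == 1),
    )


def run_ode_euler(
    params: ModelParams,
    policy: TreatmentPolicy,
    scaling: HouseholdScaling | None = None,
    init: OdeState | None = None,
    t_max: float = 3000.0,
    dt: float = 1.0,
) -> OdeTrajectory:
    """Fixed-step day-grid forward-Euler integrator (cross-check oracle).

    The branch is re-evaluated from the sign of ``M_h`` at every grid point;
    crossings are therefore resolved only to ``dt``.
    """
    scaling = scaling or HouseholdScaling()
    init = init or default_initial_state(params.econ.M0)
    p = _pack_params(params, policy, scaling)
    y = init.to_array()
    n_steps = int(np.ceil(t_max / dt))
    ts = [0.0]
    ys = [y.copy()]
    brs = [1 if y[8] <= 0 else 0]
    dy = np.empty(9)
    for k in range(n_steps):
        bankrupt = 1 if y[8] <= 0.0 else 0
        _rhs_nb(y, p, bankrupt, dy)
        y = y + dt * dy
        ts.append((k + 1) * dt)
        ys.append(y.copy())
        brs.append(1 if y[8] <= 0.0 else 0)
        if y[1] + y[2] + y[5] + y[6] < INFECTIVE_EXTINCTION:
            break
    times = np.array(ts)
    states = np.array(ys)
    branch = np.array(brs, dtype=np.int8)
    truncated = states[-1, [1, 2, 5, 6]].sum() >= INFECTIVE_EXTINCTION
    return OdeTrajectory(
        times=times,
        states=states,
        branch=branch,
        bankruptcy_intervals=_bankruptcy_intervals(times, branch),
        burden_p=float(init.total_producers - states[-1, 0]),
        burden_c=float(init.total_consumers - states[-1, 4]),
        truncated=bool(truncated),
    )


def consumer_burden(traj: OdeTrajectory) -> float:
    """Cumulative consumer infections: initial minus final susceptible consumers."""
    if traj.truncated:
        raise ValueError(
            "trajectory was truncated before extinction; burden is not final"
        )
    return traj.burden_c


def producer_burden(traj: OdeTrajectory) -> float:
    if traj.truncated:
        raise ValueError(
            "trajectory was truncated before extinction; burden is not final"
        )
    return traj.burden_p
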