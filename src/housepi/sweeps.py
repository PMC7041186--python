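"""Treatment-plane and economic-plane sweeps and the three phenomenon detectors.

A *line of demographically proportionate treatment* is the locus of
coverage pairs ``(T_p, T_c)`` administering the same total number of
treatments under the 40/60 producer/consumer split:
``0.4 T_p + 0.6 T_c = level`` (slope ``dT_p/dT_c = -3/2``).

Three named phenomena are measured on a consumer-burden grid over the
``T_p x T_c`` plane:

* **threshold** - the paradoxical benefit of reallocating treatments from
  consumers to producers along a proportionate line, measured as the
  greatest relative burden drop between the line's worst and best points
  when the best point is the more producer-heavy one;
* **weak economy** - a sharp burden collapse as the overall coverage level
  crosses the point that keeps the economy solvent, measured along the
  equal-allocation diagonal;
* **overspending** - a second-order burden *increase* when both coverages
  rise (treatment spending itself tips the economy), measured over
  adjacent grid cells.

All three are relative (dimensionless) measures, invariant to uniform
rescaling of the burden grid, and identically zero on constant grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .abm import monte_carlo_burden
from .ode import HouseholdScaling, run_ode
from .params import (
    Demography,
    ModelParams,
    TreatmentPolicy,
    compute_cpr,
    compute_tci,
)

__all__ = [
    "BurdenGrid",
    "ProportionateLine",
    "PhenomenonReport",
    "proportionate_line",
    "sweep_treatment_plane",
    "threshold_magnitude",
    "weak_economy_magnitude",
    "overspending_magnitude",
    "solvent_diagonal_burdens",
    "sweep_econ_plane",
    "reports_to_frame",
]

#: relative drop within one 0.05-level step required before a diagonal
#: decrease counts as the weak-economy jump rather than ordinary steepness
WEAK_ECONOMY_CUTOFF = 0.25
#: relative rises below this are ignored by the overspending detector
OVERSPENDING_CUTOFF = 1e-3
#: relative drops below this are integrator noise, not a threshold signal
THRESHOLD_CUTOFF = 1e-6


@dataclass(frozen=True)
class ProportionateLine:
    """Sampled segment of one demographically proportionate treatment line."""

    level: float
    points: tuple[tuple[float, float], ...]  # (T_p, T_c)

    def __iter__(self):
        return iter(self.points)


@dataclass
class BurdenGrid:
    """Cumulative-infection outcomes over a T_p x T_c grid for one economy."""

    t_p_values: np.ndarray
    t_c_values: np.ndarray
    burden_p: np.ndarray  # shape (len(t_p_values), len(t_c_values))
    burden_c: np.ndarray
    c_c: float
    c_t: float
    engine: str  # "ode" or "abm(<n_reps>)"
    se_c: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = (len(self.t_p_values), len(self.t_c_values))
        if self.burden_p.shape != shape or self.burden_c.shape != shape:
            raise ValueError("burden matrices must match the grid axes")

    def interp_consumer(self, t_p: float, t_c: float) -> float:
        """Bilinear interpolation of consumer burden at one policy point."""
        return float(_bilinear(self.t_p_values, self.t_c_values, self.burden_c, t_p, t_c))

    def to_frame(self) -> pd.DataFrame:
        tp, tc = np.meshgrid(self.t_p_values, self.t_c_values, indexing="ij")
        frame = pd.DataFrame(
            {
                "T_p": tp.ravel(),
                "T_c": tc.ravel(),
                "burden_p": self.burden_p.ravel(),
                "burden_c": self.burden_c.ravel(),
            }
        )
        frame["C_c"] = self.c_c
        frame["C_t"] = self.c_t
        frame["engine"] = self.engine
        if self.se_c is not None:
            frame["se_c"] = self.se_c.ravel()
        return frame


@dataclass(frozen=True)
class PhenomenonReport:
    """Scalar phenomenon magnitudes at one (C_c, C_t) economy."""

    c_c: float
    c_t: float
    cpr: float
    tci: float
    weak_economy_mag: float
    threshold_mag: float
    overspending_mag: float


def _bilinear(xv: np.ndarray, yv: np.ndarray, z: np.ndarray, x, y):
    """Bilinear interpolation on a rectilinear grid (clamped to the hull)."""
    x = np.clip(x, xv[0], xv[-1])
    y = np.clip(y, yv[0], yv[-1])
    i = np.clip(np.searchsorted(xv, x) - 1, 0, len(xv) - 2)
    j = np.clip(np.searchsorted(yv, y) - 1, 0, len(yv) - 2)
    fx = (x - xv[i]) / (xv[i + 1] - xv[i])
    fy = (y - yv[j]) / (yv[j + 1] - yv[j])
    return (
        z[i, j] * (1 - fx) * (1 - fy)
        + z[i + 1, j] * fx * (1 - fy)
        + z[i, j + 1] * (1 - fx) * fy
        + z[i + 1, j + 1] * fx * fy
    )


def proportionate_line(
    level: float,
    n_points: int = 50,
    producer_fraction: float = 0.4,
) -> ProportionateLine:
    """Sample the segment of ``w_p T_p + w_c T_c = level`` inside the unit square.

    ``w_p, w_c`` are the population shares (0.4/0.6 at the default
    demography).  ``level`` is the effective overall coverage; levels 0 and
    1 degenerate to the corners (0, 0) and (1, 1).
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError("level must lie in [0, 1]")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    w_p = producer_fraction
    w_c = 1.0 - producer_fraction
    # T_p range for which T_c = (level - w_p T_p)/w_c stays inside [0, 1]
    lo = max(0.0, (level - w_c) / w_p)
    hi = min(1.0, level / w_p)
    if hi < lo:
        raise ValueError("empty proportionate segment (degenerate weights)")
    if hi - lo < 1e-12:
        tps = np.array([0.5 * (lo + hi)])
    else:
        tps = np.linspace(lo, hi, n_points)
    pts = tuple((float(tp), float((level - w_p * tp) / w_c)) for tp in tps)
    return ProportionateLine(level=level, points=pts)


def sweep_treatment_plane(
    params: ModelParams,
    demog: Demography | None = None,
    engine: str = "ode",
    resolution: int = 21,
    seed: int | None = None,
    n_reps: int = 500,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_days: int = 1000,
) -> BurdenGrid:
    """Burden grid over a uniform ``resolution x resolution`` coverage grid.

    The ODE engine is deterministic; the ABM engine averages ``n_reps``
    seeded replicates per cell and carries the consumer-burden standard
    error.  A cell whose simulation fails raises with its (T_p, T_c).
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    if engine not in ("ode", "abm"):
        raise ValueError(f"unknown engine {engine!r}")
    demog = demog or Demography()
    t_values = np.linspace(0.0, 1.0, resolution)
    shape = (resolution, resolution)
    burden_p = np.empty(shape)
    burden_c = np.empty(shape)
    se_c = np.empty(shape) if engine == "abm" else None
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    cell_seeds = ss.spawn(resolution * resolution)
    scaling = HouseholdScaling.from_demography(demog)
    for i, t_p in enumerate(t_values):
        for j, t_c in enumerate(t_values):
            policy = TreatmentPolicy(float(t_p), float(t_c))
            try:
                if engine == "ode":
                    traj = run_ode(params, policy, scaling, rtol=rtol, atol=atol)
                    burden_p[i, j] = traj.burden_p
                    burden_c[i, j] = traj.burden_c
                else:
                    summary = monte_carlo_burden(
                        params, demog, policy,
                        n_reps=n_reps,
                        seed=cell_seeds[i * resolution + j],
                        max_days=max_days,
                    )
                    burden_p[i, j] = summary.mean_burden_p
                    burden_c[i, j] = summary.mean_burden_c
                    se_c[i, j] = summary.se_burden_c
            except Exception as exc:
                raise RuntimeError(
                    f"sweep cell (T_p={t_p:.3f}, T_c={t_c:.3f}) failed: {exc}"
                ) from exc
    return BurdenGrid(
        t_p_values=t_values,
        t_c_values=t_values,
        burden_p=burden_p,
        burden_c=burden_c,
        c_c=params.econ.C_c,
        c_t=params.econ.C_t,
        engine="ode" if engine == "ode" else f"abm({n_reps})",
        se_c=se_c,
    )


def _line_drop(grid: BurdenGrid, pts: np.ndarray) -> float:
    """Producer-heavy-favouring relative drop along one sampled line."""
    vals = np.array([grid.interp_consumer(tp, tc) for tp, tc in pts])
    vmax = vals.max()
    if vmax <= 0:
        return 0.0
    i_min = int(vals.argmin())
    i_max = int(vals.argmax())
    if pts[i_min, 0] > pts[i_max, 0]:  # benefit from the producer-heavy side
        return float((vmax - vals[i_min]) / vmax)
    return 0.0


def threshold_magnitude(
    grid: BurdenGrid,
    n_lines: int = 21,
    n_points: int = 41,
    producer_fraction: float = 0.4,
    cutoff: float = THRESHOLD_CUTOFF,
    baseline: BurdenGrid | None = None,
) -> float:
    """Greatest relative consumer-burden drop along any proportionate line.

    For each sampled coverage level, the consumer burden is interpolated
    along the line; the line's drop is ``(max - min)/max`` *provided* the
    minimising point is more producer-heavy (higher T_p) than the
    maximising point - the signature of the threshold phenomenon - and 0
    otherwise.  Returns the maximum drop over lines, in [0, 1]; drops below
    ``cutoff`` count as numerical noise.

    Reallocating treatment towards producers already helps consumers
    slightly in the economy-free system (treated producers transmit for a
    shorter time); passing the always-solvent sweep of the same treatment
    plane as ``baseline`` subtracts that line-by-line, leaving only the
    economy-induced excess.
    """
    best = 0.0
    for level in np.linspace(0.0, 1.0, n_lines):
        line = proportionate_line(level, n_points, producer_fraction)
        pts = np.array(line.points)
        drop = _line_drop(grid, pts)
        if baseline is not None:
            drop -= _line_drop(baseline, pts)
        best = max(best, drop)
    return best if best >= cutoff else 0.0


def solvent_diagonal_burdens(
    params: ModelParams,
    levels: np.ndarray,
    scaling: HouseholdScaling | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Consumer burdens at ``T_p = T_c = level`` with the economy disabled.

    Solvent-branch epidemiology is independent of money, so running with
    zero consumption and free treatment (bankruptcy then impossible) gives
    the economy-free counterfactual against which the weak-economy jump is
    measured.  Depends only on the epidemiological parameters and levels,
    not on ``C_c``/``C_t``, so one ladder serves a whole economic plane.
    """
    solvent = replace(params, econ=replace(params.econ, C_c=0.0, C_t=0.0))
    out = np.empty(len(levels))
    for k, level in enumerate(levels):
        traj = run_ode(
            solvent, TreatmentPolicy(float(level), float(level)), scaling,
            rtol=rtol, atol=atol,
        )
        out[k] = traj.burden_c
    return out


def weak_economy_magnitude(
    grid: BurdenGrid,
    level_step: float = 0.05,
    cutoff: float = WEAK_ECONOMY_CUTOFF,
    solvent_diagonal: np.ndarray | None = None,
) -> float:
    """Sharpest relative burden collapse along the equal-allocation diagonal.

    Samples consumer burden at ``T_p = T_c = level`` on a uniform level
    ladder and returns the largest relative decrease between adjacent
    levels, or 0 if no step is at least ``cutoff`` (ordinary smooth
    improvement does not count as the phenomenon).

    Treatment alone can also produce steep declines (near the critical
    coverage of the economy-free system); passing the matching
    ``solvent_diagonal`` ladder (see :func:`solvent_diagonal_burdens`)
    subtracts that baseline steepness so only the economy-induced excess
    is scored.
    """
    levels = np.arange(0.0, 1.0 + 1e-12, level_step)
    vals = np.array([grid.interp_consumer(t, t) for t in levels])
    baseline = np.zeros(len(levels) - 1)
    if solvent_diagonal is not None:
        if len(solvent_diagonal) != len(levels):
            raise ValueError("solvent_diagonal must be sampled on the same ladder")
        ref = np.asarray(solvent_diagonal, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            baseline = np.where(
                ref[:-1] > 0, (ref[:-1] - ref[1:]) / ref[:-1], 0.0
            )
    mag = 0.0
    for k in range(len(levels) - 1):
        if vals[k] > 0:
            drop = (vals[k] - vals[k + 1]) / vals[k] - baseline[k]
            mag = max(mag, drop)
    return float(mag) if mag >= cutoff else 0.0


def overspending_magnitude(
    grid: BurdenGrid, cutoff: float = OVERSPENDING_CUTOFF
) -> float:
    """Largest relative burden rise when moving to higher coverage in both roles.

    Compares each cell with its diagonal neighbour at strictly higher
    ``(T_p, T_c)``; a monotone non-increasing grid scores 0.  Rises below
    ``cutoff`` are treated as numerical noise.
    """
    b = grid.burden_c
    base = b[:-1, :-1]
    upper = b[1:, 1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(base > 0, (upper - base) / base, 0.0)
    mag = float(rel.max(initial=0.0))
    return mag if mag >= cutoff else 0.0


def sweep_econ_plane(
    params: ModelParams,
    demog: Demography | None = None,
    c_c_values: np.ndarray | None = None,
    c_t_values: np.ndarray | None = None,
    resolution: int = 11,
    t_resolution: int = 21,
    engine: str = "ode",
    seed: int | None = None,
    n_reps: int = 500,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> list[PhenomenonReport]:
    """Phenomenon magnitudes over the (C_c, C_t) economic plane.

    Defaults cover consumption 0-50 and treatment cost 0-500 on a
    ``resolution x resolution`` grid, each cell scored from a
    ``t_resolution x t_resolution`` treatment-plane sweep.  Failing cells
    raise with their coordinates.
    """
    demog = demog or Demography()
    if c_c_values is None:
        c_c_values = np.linspace(0.0, 50.0, resolution)
    if c_t_values is None:
        c_t_values = np.linspace(0.0, 500.0, resolution)
    if np.any(np.asarray(c_c_values) < 0) or np.any(np.asarray(c_c_values) > 50):
        raise ValueError("C_c values must lie within [0, 50]")
    if np.any(np.asarray(c_t_values) < 0) or np.any(np.asarray(c_t_values) > 500):
        raise ValueError("C_t values must lie within [0, 500]")
    # economy-neutral counterfactual: with zero consumption and free
    # treatment the solvent branch never exits, so one sweep serves every
    # (C_c, C_t) cell as the baseline for the threshold and weak-economy
    # detectors
    solvent_grid = None
    solvent_diag = None
    if engine == "ode":
        neutral = replace(params, econ=replace(params.econ, C_c=0.0, C_t=0.0))
        solvent_grid = sweep_treatment_plane(
            neutral, demog, engine="ode", resolution=t_resolution,
            rtol=rtol, atol=atol,
        )
        levels = np.arange(0.0, 1.0 + 1e-12, 0.05)
        solvent_diag = np.array(
            [solvent_grid.interp_consumer(t, t) for t in levels]
        )
    reports: list[PhenomenonReport] = []
    for c_c in np.asarray(c_c_values, dtype=float):
        for c_t in np.asarray(c_t_values, dtype=float):
            cell = replace(params, econ=replace(params.econ, C_c=c_c, C_t=c_t))
            try:
                grid = sweep_treatment_plane(
                    cell, demog, engine=engine, resolution=t_resolution,
                    seed=seed, n_reps=n_reps, rtol=rtol, atol=atol,
                )
                reports.append(
                    PhenomenonReport(
                        c_c=float(c_c),
                        c_t=float(c_t),
                        cpr=compute_cpr(cell.econ, demog),
                        tci=compute_tci(cell.econ, demog),
                        weak_economy_mag=weak_economy_magnitude(
                            grid, solvent_diagonal=solvent_diag
                        ),
                        threshold_mag=threshold_magnitude(
                            grid, baseline=solvent_grid
                        ),
                        overspending_mag=overspending_magnitude(grid),
                    )
                )
            except Exception as exc:
                raise RuntimeError(
                    f"economic cell (C_c={c_c:.2f}, C_t={c_t:.2f}) failed: {exc}"
                ) from exc
    return reports


def reports_to_frame(reports: list[PhenomenonReport]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in reports])
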