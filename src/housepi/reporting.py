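"""Tidy-CSV writers, run manifests and figure rendering.

Every command writes a ``manifest.json`` next to its outputs listing the
resolved configuration, the seeds, package/library versions, wall-clock
timings and a SHA-256 checksum per output file.  The manifest is written
even when a run fails part-way (with ``status: "failed"``), so partial
output is always identifiable.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .abm import AbmResult
from .config import Config, dump_config
from .ode import OdeTrajectory
from .sweeps import BurdenGrid, PhenomenonReport, proportionate_line, reports_to_frame

__all__ = ["RunManifest", "ManifestWriter", "write_outputs",
           "plot_burden_heatmap", "plot_trajectory", "plot_phenomena"]


@dataclass
class RunManifest:
    command: str
    config: dict
    seed: int | None
    versions: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256
    status: str = "ok"
    error: str | None = None

    def to_json(self) -> str:
        return json.dumps(vars(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _versions() -> dict:
    import numpy
    import scipy

    return {"housepi": __version__, "numpy": numpy.__version__, "scipy": scipy.__version__}


class ManifestWriter:
    """Context manager guaranteeing a manifest lands on disk, pass or fail."""

    def __init__(self, command: str, out_dir: str | Path, config: Config | None,
                 seed: int | None):
        self.out_dir = Path(out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.manifest = RunManifest(
            command=command,
            config=dump_config(config) if config is not None else {},
            seed=seed,
            versions=_versions(),
        )
        self._t0 = time.perf_counter()

    def add(self, path: Path) -> None:
        self.manifest.outputs[str(path.relative_to(self.out_dir))] = _sha256(path)

    def __enter__(self) -> "ManifestWriter":
        return self

    def __exit__(self, exc_type, exc, tb) -> bool:
        self.manifest.timings["wall_seconds"] = round(
            time.perf_counter() - self._t0, 3
        )
        if exc is not None:
            self.manifest.status = "failed"
            self.manifest.error = f"{exc_type.__name__}: {exc}"
        (self.out_dir / "manifest.json").write_text(self.manifest.to_json())
        return False  # never swallow the exception


def write_outputs(
    result: AbmResult | OdeTrajectory | BurdenGrid | list,
    out_dir: str | Path,
    config: Config | None = None,
    seed: int | None = None,
    command: str = "run",
) -> RunManifest:
    """Write a result's tidy CSV representation plus its manifest."""
    with ManifestWriter(command, out_dir, config, seed) as mw:
        out = Path(out_dir)
        if isinstance(result, AbmResult):
            path = out / "trajectory.csv"
            result.to_frame().to_csv(path, index=False)
            mw.add(path)
            summary = out / "summary.csv"
            pd.DataFrame(
                [
                    {
                        "burden_p": result.final_burden_p,
                        "burden_c": result.final_burden_c,
                        "days": len(result.trajectory),
                        "truncated": result.truncated,
                        "seed": result.seed,
                    }
                ]
            ).to_csv(summary, index=False)
            mw.add(summary)
        elif isinstance(result, OdeTrajectory):
            path = out / "trajectory.csv"
            result.to_frame().to_csv(path, index=False)
            mw.add(path)
        elif isinstance(result, BurdenGrid):
            path = out / "grid.csv"
            result.to_frame().to_csv(path, index=False)
            mw.add(path)
        elif isinstance(result, list) and all(
            isinstance(r, PhenomenonReport) for r in result
        ):
            path = out / "phenomena.csv"
            reports_to_frame(result).to_csv(path, index=False)
            mw.add(path)
        else:
            raise TypeError(f"no writer for result type {type(result).__name__}")
    return mw.manifest


# -- figures ----------------------------------------------------------------


def plot_burden_heatmap(
    grid: BurdenGrid | pd.DataFrame,
    path: str | Path,
    value: str = "burden_c",
    n_lines: int = 9,
) -> Path:
    """Consumer-burden heatmap over the T_c x T_p plane.

    Lines of demographically proportionate treatment are overlaid in white.
    Accepts either a grid object or its tidy-CSV frame, so a published CSV
    regenerates an identical figure.
    """
    frame = grid.to_frame() if isinstance(grid, BurdenGrid) else grid
    pivot = frame.pivot(index="T_p", columns="T_c", values=value)
    fig, ax = plt.subplots(figsize=(6, 5))
    mesh = ax.pcolormesh(
        pivot.columns.to_numpy(), pivot.index.to_numpy(), pivot.to_numpy(),
        shading="nearest", cmap="viridis",
    )
    for level in np.linspace(0.1, 0.9, n_lines):
        pts = np.array(proportionate_line(level, 50).points)
        ax.plot(pts[:, 1], pts[:, 0], color="white", lw=1.0)
    ax.set_xlabel("$T_c$ (consumer coverage)")
    ax.set_ylabel("$T_p$ (producer coverage)")
    ax.set_title(value)
    fig.colorbar(mesh, ax=ax)
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_trajectory(traj: OdeTrajectory | pd.DataFrame, path: str | Path) -> Path:
    """Infective compartments and money over time, bankruptcy shaded."""
    frame = traj.to_frame() if isinstance(traj, OdeTrajectory) else traj
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    for col, label in (
        ("I_p", "producers untreated"),
        ("I_p_plus", "producers treated"),
        ("I_c", "consumers untreated"),
        ("I_c_plus", "consumers treated"),
    ):
        ax1.plot(frame["t"], frame[col], label=label)
    ax1.set_ylabel("infectives")
    ax1.legend(fontsize=8)
    ax2.plot(frame["t"], frame["M_h"], color="black")
    ax2.axhline(0.0, color="red", lw=0.8, ls="--")
    bankrupt = frame["bankrupt"].to_numpy().astype(bool)
    if bankrupt.any():
        ax2.fill_between(
            frame["t"], frame["M_h"].min(), frame["M_h"].max(),
            where=bankrupt, alpha=0.15, color="red",
        )
    ax2.set_ylabel("household money $M_h$")
    ax2.set_xlabel("time (days)")
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_phenomena(
    reports: list[PhenomenonReport] | pd.DataFrame,
    path: str | Path,
    which: str = "threshold_mag",
) -> Path:
    """Phenomenon-magnitude heatmap over the C_c x C_t economic plane."""
    frame = reports_to_frame(reports) if isinstance(reports, list) else reports
    pivot = frame.pivot(index="c_t", columns="c_c", values=which)
    fig, ax = plt.subplots(figsize=(6, 5))
    mesh = ax.pcolormesh(
        pivot.columns.to_numpy(), pivot.index.to_numpy(), pivot.to_numpy(),
        shading="nearest", cmap="Blues",
    )
    ax.set_xlabel("$C_c$ (consumption per consumer)")
    ax.set_ylabel("$C_t$ (treatment cost)")
    ax.set_title(which)
    fig.colorbar(mesh, ax=ax)
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
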