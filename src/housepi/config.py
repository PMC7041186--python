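"""Configuration loading, validation and provenance capture.

A configuration file (YAML or JSON) carries up to five sections -- ``epi``,
``econ``, ``demography``, ``policy`` and ``run`` -- whose keys mirror the
model symbols (``beta_p``, ``gamma_plus_c``, ``p_p``, ``t_c`` ...).  Every
key is optional (defaults are the tabulated parameter set); unknown sections
or keys are an error, so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .params import (
    Demography,
    EconParams,
    EpiParams,
    ModelParams,
    TreatmentPolicy,
    compute_cpr,
    compute_tci,
)

__all__ = ["RunOptions", "Config", "load_config", "dump_config", "write_provenance"]

_EPI_KEYS = set(EpiParams.__dataclass_fields__)
_ECON_KEYS = {"p_p", "c_c", "c_t", "m0"}
_DEMOG_KEYS = set(Demography.__dataclass_fields__)
_POLICY_KEYS = {"t_p", "t_c"}
_RUN_KEYS = {
    "seed",
    "rate_conversion",
    "money_scale",
    "max_days",
    "t_max",
    "rtol",
    "atol",
    "engine",
    "n_reps",
    "resolution",
    "t_resolution",
}
_SECTIONS = {"epi", "econ", "demography", "policy", "run"}


@dataclass(frozen=True)
class RunOptions:
    seed: int = 0
    max_days: int = 1000
    t_max: float = 3000.0
    rtol: float = 1e-8
    atol: float = 1e-10
    engine: str = "ode"
    n_reps: int = 500
    resolution: int = 21
    t_resolution: int = 21


@dataclass(frozen=True)
class Config:
    params: ModelParams
    demography: Demography
    policy: TreatmentPolicy
    run: RunOptions

    def derived_indices(self) -> dict[str, float]:
        return {
            "cpr": compute_cpr(self.params.econ, self.demography),
            "tci": compute_tci(self.params.econ, self.demography),
        }


def _check_keys(section: str, mapping: dict, allowed: set[str]) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) in section {section!r}: {sorted(unknown)}; "
            f"allowed: {sorted(allowed)}"
        )


def _build(raw: dict) -> Config:
    if not isinstance(raw, dict):
        raise ValueError("configuration root must be a mapping")
    _check_keys("<root>", raw, _SECTIONS)
    epi_raw = dict(raw.get("epi") or {})
    econ_raw = dict(raw.get("econ") or {})
    demog_raw = dict(raw.get("demography") or {})
    policy_raw = dict(raw.get("policy") or {})
    run_raw = dict(raw.get("run") or {})
    _check_keys("epi", epi_raw, _EPI_KEYS)
    _check_keys("econ", econ_raw, _ECON_KEYS)
    _check_keys("demography", demog_raw, _DEMOG_KEYS)
    _check_keys("policy", policy_raw, _POLICY_KEYS)
    _check_keys("run", run_raw, _RUN_KEYS)

    epi = EpiParams(**epi_raw)
    econ = EconParams(
        P_p=econ_raw.get("p_p", 50.0),
        C_c=econ_raw.get("c_c", 30.0),
        C_t=econ_raw.get("c_t", 250.0),
        M0=econ_raw.get("m0", 500.0),
    )
    if "producers_range" in demog_raw:
        demog_raw["producers_range"] = tuple(demog_raw["producers_range"])
    if "consumers_range" in demog_raw:
        demog_raw["consumers_range"] = tuple(demog_raw["consumers_range"])
    demography = Demography(**demog_raw)
    policy = TreatmentPolicy(
        T_p=policy_raw.get("t_p", 0.0), T_c=policy_raw.get("t_c", 0.0)
    )
    conversion = run_raw.pop("rate_conversion", "identity")
    money_scale = run_raw.pop("money_scale", "per_household")
    params = ModelParams(
        epi=epi, econ=econ, rate_conversion=conversion, money_scale=money_scale
    )
    run = RunOptions(**run_raw)
    return Config(params=params, demography=demography, policy=policy, run=run)


def load_config(path: str | Path | None = None) -> Config:
    """Load and validate a configuration file; ``None`` gives full defaults."""
    if path is None:
        return _build({})
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    raw = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else (
        json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    )
    return _build(raw or {})


def dump_config(config: Config) -> dict:
    """Fully resolved configuration as a plain mapping (reload-stable)."""
    econ = config.params.econ
    return {
        "epi": asdict(config.params.epi),
        "econ": {"p_p": econ.P_p, "c_c": econ.C_c, "c_t": econ.C_t, "m0": econ.M0},
        "demography": {
            **asdict(config.demography),
            "producers_range": list(config.demography.producers_range),
            "consumers_range": list(config.demography.consumers_range),
        },
        "policy": {"t_p": config.policy.T_p, "t_c": config.policy.T_c},
        "run": {
            **asdict(config.run),
            "rate_conversion": config.params.rate_conversion,
            "money_scale": config.params.money_scale,
        },
    }


def write_provenance(config: Config, path: str | Path) -> dict:
    """Echo the resolved parameter set (plus derived CPR/TCI) to a JSON sidecar."""
    payload = {
        "config": dump_config(config),
        "derived": config.derived_indices(),
        "seed": config.run.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
    return payload
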