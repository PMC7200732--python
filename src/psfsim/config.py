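"""Configuration files, result serialization, and run manifests.

Configs are YAML or JSON with up to three blocks::

    preset: reference            # optional: start from the published values
    parameters:             # Table-style trait names
      s_m: 0.35
      s_p: 0.03
      ...
    run:
      n: 499
      k: 5
      steps: 3000
      replacement_fraction: 0.10
      seeds_per_tree: 10
      seed: 17
    experiment:             # optional: ablation / sweep / pso settings
      ablation_mode: remove_pathogens
      trigger_step: 800

Unknown keys are rejected so typos cannot silently revert to defaults.
"""

from __future__ import annotations

import json
import platform
import subprocess
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import SUBSTREAMS, Trajectory
from .parameters import (
    TRAIT_BOUNDS,
    ParameterSet,
    reference_parameterization,
    from_flat_dict,
)

__all__ = ["RunConfig", "load_config", "write_outputs", "ConfigError"]


class ConfigError(ValueError):
    pass


_RUN_KEYS = {
    "n", "k", "steps", "replacement_fraction", "seeds_per_tree", "seed",
    "literal_logistic", "propagule_mode", "recruit_init",
}
_EXPERIMENT_KEYS = {
    "ablation_mode", "trigger_step", "delete_populations",
    "sweep_runs", "pso_swarms", "pso_particles", "pso_steps_per_stage",
}


@dataclass(frozen=True)
class RunConfig:
    params: ParameterSet
    experiment: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "parameters": self.params.to_flat_dict(),
            "run": {
                "n": self.params.n,
                "k": self.params.k,
                "steps": self.params.steps,
                "replacement_fraction": self.params.replacement_fraction,
                "seeds_per_tree": self.params.seeds_per_tree,
                "seed": self.params.rng_seed,
                "literal_logistic": self.params.literal_logistic,
                "propagule_mode": self.params.propagule_mode,
                "recruit_init": self.params.recruit_init,
            },
            "experiment": dict(self.experiment),
        }


def _build_params(raw: dict) -> ParameterSet:
    preset = raw.pop("preset", None)
    traits = dict(raw.pop("parameters", {}) or {})
    run = dict(raw.pop("run", {}) or {})
    if raw.keys() - {"experiment"}:
        raise ConfigError(f"unknown top-level keys: {sorted(raw.keys() - {'experiment'})}")
    unknown_traits = traits.keys() - TRAIT_BOUNDS.keys() - {"zeta"}
    if unknown_traits:
        raise ConfigError(f"unknown parameter keys: {sorted(unknown_traits)}")
    unknown_run = run.keys() - _RUN_KEYS
    if unknown_run:
        raise ConfigError(f"unknown run keys: {sorted(unknown_run)}")
    for name, value in traits.items():
        if name in TRAIT_BOUNDS:
            lo, hi = TRAIT_BOUNDS[name]
            if not (lo <= float(value) <= hi):
                raise ConfigError(f"{name} = {value} outside range [{lo}, {hi}]")
    run_settings = {("rng_seed" if k == "seed" else k): v for k, v in run.items()}
    zeta = traits.pop("zeta", None)
    if zeta is not None:
        run_settings["zeta_min"] = float(zeta)
    if preset is not None:
        if preset != "reference":
            raise ConfigError(f"unknown preset {preset!r}")
        base = reference_parameterization(**run_settings)
        return base.replace(**traits) if traits else base
    missing = TRAIT_BOUNDS.keys() - traits.keys()
    if missing:
        raise ConfigError(f"missing parameters (or use 'preset: reference'): {sorted(missing)}")
    return from_flat_dict(traits, **run_settings)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    raw = dict(raw)
    experiment = dict(raw.pop("experiment", {}) or {})
    unknown_exp = experiment.keys() - _EXPERIMENT_KEYS
    if unknown_exp:
        raise ConfigError(f"unknown experiment keys: {sorted(unknown_exp)}")
    params = _build_params(raw)
    return RunConfig(params=params, experiment=experiment)


def save_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def _git_hash() -> str | None:
    try:
        return subprocess.run(
            ["git", "rev-parse", "HEAD"], capture_output=True, text=True,
            timeout=5, check=True,
        ).stdout.strip()
    except Exception:
        return None


def write_outputs(
    outdir: str | Path,
    trajectory: Trajectory | None = None,
    metrics: dict | None = None,
    records: pd.DataFrame | None = None,
    config: RunConfig | None = None,
    seed: int | None = None,
    extra_tables: dict[str, pd.DataFrame] | None = None,
    wall_time: float | None = None,
) -> dict:
    """Write run artifacts (CSV/JSON) and a manifest; return the manifest.

    Tables are CSV; ``records.csv`` is append-safe so sweeps can persist
    incrementally.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    if trajectory is not None:
        k = trajectory.abundance.shape[1]
        df = pd.DataFrame(
            trajectory.abundance, columns=[f"species_{j}" for j in range(k)]
        )
        df.insert(0, "step", np.arange(len(df)))
        df.to_csv(outdir / "trajectory.csv", index=False)
        written.append("trajectory.csv")
    if metrics is not None:
        pd.DataFrame([metrics]).to_csv(outdir / "metrics.csv", index=False)
        written.append("metrics.csv")
    if records is not None:
        target = outdir / "records.csv"
        records.to_csv(target, mode="a", header=not target.exists(), index=False)
        written.append("records.csv")
    if config is not None:
        (outdir / "params.json").write_text(json.dumps(config.to_dict(), indent=2))
        written.append("params.json")
    for name, table in (extra_tables or {}).items():
        table.to_csv(outdir / f"{name}.csv", index=False)
        written.append(f"{name}.csv")
    manifest = {
        "psfsim_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed if seed is not None else (
            config.params.rng_seed if config is not None else None
        ),
        "substreams": list(SUBSTREAMS),
        "git_hash": _git_hash(),
        "wall_time_s": wall_time,
        "written": written,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
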