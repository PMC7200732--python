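"""Experiment designs: random parameter sweeps, ablations, fixed microbiomes.

Three boolean outcome labels summarize a run:

* ``coexistence`` — all k plant species persist to the end;
* ``strong_negative_feedback`` — the initial maximum-strength pairwise
  feedback I_max is below -1.5;
* ``abundance_correlation`` — rho(I_s) > 0.8, sigma(I_s) > 0.02,
  I_max < 0, and plant, mutualist, and pathogen richness all equal k.

Ablations let a run proceed normally to a trigger step and then remove a
model component: the recruitment effect of all microbes, of pathogens
only, of mutualists only, or all microbial dynamics (fixing per-species
mean microbiomes).  Control and ablated runs share the same random
substreams, so they are identical up to the trigger step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from . import metrics as metrics_mod
from .engine import Simulation, Trajectory
from .parameters import ParameterSet, sample_random

__all__ = [
    "AblationSpec",
    "RunRecord",
    "run_with_metrics",
    "random_sweep",
    "ablation_run",
    "classify_outcomes",
    "ABLATION_MODES",
]

ABLATION_MODES = (
    "none",
    "remove_all_microbes",
    "remove_pathogens",
    "remove_mutualists",
    "fix_microbiomes",
)

#: Default intervention step: the published ablations trigger after the
#: equivalent of 4 K years, i.e. 800 five-year steps.
DEFAULT_TRIGGER_STEP = 800

RHO_THRESHOLD = 0.8
SIGMA_THRESHOLD = 0.02
STRONG_NEGATIVE_THRESHOLD = -1.5


@dataclass(frozen=True)
class AblationSpec:
    mode: str = "none"
    trigger_step: int = DEFAULT_TRIGGER_STEP
    delete_populations: bool = False  # also zero the microbial fields

    def __post_init__(self) -> None:
        if self.mode not in ABLATION_MODES:
            raise ValueError(f"unknown ablation mode {self.mode!r}")
        if self.trigger_step < 0:
            raise ValueError("trigger_step must be >= 0")


@dataclass
class RunRecord:
    """One sweep row: parameters plus metrics plus outcome labels."""

    params: dict[str, float]
    run_metrics: dict[str, float]
    labels: dict[str, bool] = field(default_factory=dict)
    seed: int | None = None
    error: str | None = None

    def to_row(self) -> dict:
        row: dict = {"seed": self.seed, "error": self.error}
        row.update(self.params)
        row.update(self.run_metrics)
        row.update(self.labels)
        return row


def _labels_from_metrics(m: dict, k: int) -> dict[str, bool]:
    i_max = m.get("I_max_initial", float("nan"))
    return {
        "coexistence": bool(m["plant_richness"] == k),
        "strong_negative_feedback": bool(i_max < STRONG_NEGATIVE_THRESHOLD),
        "abundance_correlation": bool(
            (m["rho"] > RHO_THRESHOLD)
            and (m["sigma_Is"] > SIGMA_THRESHOLD)
            and (i_max < 0)
            and (m["plant_richness"] == k)
            and (m["mutualist_richness"] == k)
            and (m["pathogen_richness"] == k)
        ),
    }


def run_with_metrics(
    params: ParameterSet,
    seed: int | None = None,
    callbacks: Iterable[Callable[[Simulation, int], None]] = (),
) -> tuple[Trajectory, RunRecord]:
    """Execute one run plus the initial-feedback measurement and labelling."""
    initial = metrics_mod.measure_initial_psf(params, seed=seed)
    sim = Simulation(params, seed=seed)
    traj = sim.run(callbacks=tuple(callbacks))
    m = metrics_mod.summarize_run(sim, traj, initial=initial)
    record = RunRecord(
        params=params.to_flat_dict(),
        run_metrics=m,
        labels=_labels_from_metrics(m, params.k),
        seed=seed if seed is not None else params.rng_seed,
    )
    return traj, record


def random_sweep(
    n_runs: int,
    rng: np.random.Generator,
    progress: Callable[[int], None] | None = None,
    **run_settings,
) -> pd.DataFrame:
    """Run ``n_runs`` independent simulations at random parameterizations.

    Each run draws its traits uniformly from the admissible ranges and
    its own substream seed from ``rng``; failures are recorded in the
    ``error`` column rather than aborting the sweep.  Returns one row per
    run (parameters, metrics, labels).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rows = []
    for i in range(n_runs):
        seed = int(rng.integers(0, 2**31 - 1))
        params = sample_random(rng, rng_seed=seed, **run_settings)
        try:
            _, record = run_with_metrics(params, seed=seed)
        except Exception as exc:  # individual failures must not kill a sweep
            record = RunRecord(
                params=params.to_flat_dict(), run_metrics={}, seed=seed,
                error=f"{type(exc).__name__}: {exc}",
            )
        rows.append(record.to_row())
        if progress is not None:
            progress(i)
    return pd.DataFrame(rows)


def psf_screen(
    n_draws: int,
    rng: np.random.Generator,
    **run_settings,
) -> pd.DataFrame:
    """Random-parameter screen of initial feedback strength only.

    The strong-negative-feedback label depends solely on the initial
    50-step no-mortality measurement, not on the full run, so parameter
    space can be screened for it at a fraction of a full sweep's cost.
    Returns one row per draw: parameters, initial I_max/I_min, and the
    strong_negative_feedback label.
    """
    rows = []
    for _ in range(n_draws):
        seed = int(rng.integers(0, 2**31 - 1))
        params = sample_random(rng, rng_seed=seed, **run_settings)
        report = metrics_mod.measure_initial_psf(params, seed=seed)
        row = dict(params.to_flat_dict())
        row["seed"] = seed
        row["I_max_initial"] = report.I_max
        row["I_min_initial"] = report.I_min
        row["strong_negative_feedback"] = bool(
            report.I_max < STRONG_NEGATIVE_THRESHOLD
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _make_ablation_callback(spec: AblationSpec) -> Callable[[Simulation, int], None]:
    def callback(sim: Simulation, step: int) -> None:
        if step != spec.trigger_step or spec.mode == "none":
            return
        if spec.mode == "remove_all_microbes":
            sim.mutualist_effects = False
            sim.pathogen_effects = False
        elif spec.mode == "remove_pathogens":
            sim.pathogen_effects = False
        elif spec.mode == "remove_mutualists":
            sim.mutualist_effects = False
        elif spec.mode == "fix_microbiomes":
            _fix_microbiomes(sim)
        if spec.delete_populations and spec.mode != "fix_microbiomes":
            if not sim.pathogen_effects:
                sim.state.pathogens[:] = 0.0
            if not sim.mutualist_effects:
                sim.state.mutualists[:] = 0.0

    return callback


def _fix_microbiomes(sim: Simulation) -> None:
    """Freeze microbial dynamics at per-host-species mean communities.

    The mean mutualist and pathogen community over individuals of each
    host species at the trigger step becomes the fixed microbiome of
    every subsequent recruit of that species; existing adults are also
    assigned their species mean, and competition and immigration stop.
    """
    k = sim.params.k
    mean_mut = np.zeros((k, k))
    mean_path = np.zeros((k, k))
    for j in range(k):
        mask = sim.state.species == j
        if mask.any():
            mean_mut[j] = sim.state.mutualists[mask].mean(axis=0)
            mean_path[j] = sim.state.pathogens[mask].mean(axis=0)
    sim.fixed_recruit_mutualists = mean_mut
    sim.fixed_recruit_pathogens = mean_path
    sim.state.mutualists = mean_mut[sim.state.species]
    sim.state.pathogens = mean_path[sim.state.species]
    sim.freeze_microbiomes = True


def ablation_run(
    params: ParameterSet,
    spec: AblationSpec,
    seed: int | None = None,
) -> tuple[Trajectory, RunRecord]:
    """Run with a mid-run component removal at ``spec.trigger_step``."""
    if spec.trigger_step >= params.steps and spec.mode != "none":
        raise ValueError("trigger_step must fall inside the run")
    return run_with_metrics(params, seed=seed, callbacks=[_make_ablation_callback(spec)])


def classify_outcomes(records: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """(Re)apply the three outcome labels to a sweep table.

    Rows with missing metrics are flagged in ``label_valid`` and excluded
    from the class counts attached as ``DataFrame.attrs['class_counts']``.
    """
    required = [
        "plant_richness", "mutualist_richness", "pathogen_richness",
        "rho", "sigma_Is", "I_max_initial",
    ]
    richness_cols = required[:3]
    out = records.copy()
    if set(required) <= set(out.columns):
        # rho / sigma / I_max may be NaN (undefined) — comparisons treat
        # NaN as failing the gate; only missing richness voids a row.
        valid = out[richness_cols].notna().all(axis=1)
    else:
        valid = pd.Series(False, index=out.index)
    out["label_valid"] = valid
    for col in ("coexistence", "strong_negative_feedback", "abundance_correlation"):
        out[col] = False
    for idx in out.index[valid]:
        labels = _labels_from_metrics(out.loc[idx, required].to_dict(), k)
        for col, val in labels.items():
            out.loc[idx, col] = val
    out.attrs["class_counts"] = {
        col: int(out.loc[valid, col].sum())
        for col in ("coexistence", "strong_negative_feedback", "abundance_correlation")
    }
    return out
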