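"""Seedling survival and recruitment at vacated cells.

The local mutualist and pathogen communities set a seedling's survival
probability through a logistic response; recruitment among candidate
species weights survival by fitness and local seed rain, and the recruit
is a single categorical draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RecruitmentContext",
    "survival_score",
    "recruitment_probabilities",
    "draw_recruit",
    "NoCandidateError",
]


class NoCandidateError(ValueError):
    """No species has seed rain at the cell; nothing can recruit."""


def _logistic(x: np.ndarray | float, literal: bool = False) -> np.ndarray | float:
    """Standard logistic 1/(1+e^-x).

    ``literal=True`` evaluates 1/(1-e^-x) instead, an audit-only variant
    kept because it appears in print although it is singular at x=0 and
    negative for x<0; it is never the default.
    """
    if literal:
        return 1.0 / (1.0 - np.exp(-np.asarray(x, dtype=float)))
    # expit-style stable evaluation
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class RecruitmentContext:
    """Everything needed to run one recruitment trial at one cell."""

    theta_m: np.ndarray    # (k,) mutualist effect per candidate species
    theta_p: np.ndarray    # (k,) pathogen effect per candidate species
    seed_counts: np.ndarray  # (k,) local seed rain per species
    zeta: np.ndarray       # (k,) per-species fitness
    g: float
    h: float
    literal_logistic: bool = False


def survival_score(
    theta_m: np.ndarray | float,
    theta_p: np.ndarray | float,
    zeta_j: np.ndarray | float,
    g: float,
    h: float,
    literal_logistic: bool = False,
) -> np.ndarray | float:
    """Unnormalized seedling survival: zeta_j * logistic(g*(h*theta_m - theta_p)).

    Mutualists (weighted by ``h``) raise and pathogens lower the argument;
    ``g`` scales the steepness of the microbial impact.  The value lies in
    (0, zeta_j).
    """
    x = g * (h * np.asarray(theta_m, dtype=float) - np.asarray(theta_p, dtype=float))
    return zeta_j * _logistic(x, literal=literal_logistic)


def recruitment_probabilities(context: RecruitmentContext) -> np.ndarray:
    """Per-species recruitment probability at the cell.

    Proportional to local seed rain times the survival score; normalized
    to sum to 1.  Species without seeds have probability 0.
    """
    seeds = np.asarray(context.seed_counts, dtype=float)
    if np.any(seeds < 0):
        raise ValueError("negative seed counts")
    total = seeds.sum()
    if total <= 0:
        raise NoCandidateError("no seeds arrived at the cell")
    scores = survival_score(
        context.theta_m,
        context.theta_p,
        context.zeta,
        context.g,
        context.h,
        literal_logistic=context.literal_logistic,
    )
    weights = seeds * scores
    return weights / weights.sum()


def draw_recruit(probabilities: np.ndarray, rng: np.random.Generator) -> int:
    """Single categorical draw of the recruiting species."""
    p = np.asarray(probabilities, dtype=float)
    return int(rng.choice(p.shape[0], p=p))
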