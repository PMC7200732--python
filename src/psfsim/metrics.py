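"""Measurement layer: plant–soil feedback, equilibrium, and spatial metrics.

Plant–soil feedback between species A and B uses Bever's interaction
coefficient

    I_s = S(a_A) + S(b_B) - (S(a_B) + S(b_A))

where ``S(a_X)`` is the mean survival score of species-a seedlings at
cells occupied by species-X adults.  Negative I_s means both species
recruit better away from conspecifics (stabilizing feedback); a species'
focal I_s is the mean of its pairwise values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import recruitment as recruitment_mod
from .engine import LatticeState, Simulation, Trajectory
from .parameters import ParameterSet

__all__ = [
    "SurvivalMatrix",
    "FeedbackReport",
    "survival_matrix",
    "interaction_coefficient",
    "feedback_report",
    "measure_initial_psf",
    "measure_end_psf",
    "equilibrium_metric",
    "equilibrium_from_trajectory",
    "heterospecific_fraction",
    "abundance_psf_correlation",
    "summarize_run",
    "MICROBE_PRESENCE_THRESHOLD",
]

#: Lattice-total abundance above which a microbial taxon counts as present.
#: The continuous dynamics only drive taxa to zero asymptotically, so
#: richness needs a cut-off; 0.01 is one percent of a single tree's
#: carrying capacity.
MICROBE_PRESENCE_THRESHOLD = 0.01

# The initial-feedback protocol: microbial communities equilibrate on
# their hosts for this many steps without any host mortality.
INITIAL_PSF_STEPS = 50


@dataclass(frozen=True)
class SurvivalMatrix:
    """S[a, A]: mean survival of species-a seedlings beneath species-A adults.

    Entries are NaN for adult species absent from the lattice.
    """

    S: np.ndarray  # (k, k); rows: seedling species, columns: adult species

    @property
    def k(self) -> int:
        return self.S.shape[0]


@dataclass(frozen=True)
class FeedbackReport:
    survival: SurvivalMatrix
    pairwise_Is: np.ndarray    # (k, k) symmetric, NaN diagonal / absent pairs
    focal_Is: np.ndarray       # (k,) mean of pairwise values per species
    I_max: float               # least-negative (maximum) defined pairwise I_s
    I_min: float               # most-negative defined pairwise I_s
    rho: float                 # Spearman rho of focal_Is vs abundance (NaN if undefined)
    sigma_Is: float            # sample s.d. of focal_Is across species


def survival_matrix(
    sim: Simulation,
    state: LatticeState | None = None,
    include_fitness: bool = False,
) -> SurvivalMatrix:
    """Mean survival of every seedling species beneath every adult species.

    By default the entries are the microbially mediated survival
    component ``logistic(g*(h*theta_m - theta_p))`` alone: fitness
    differences between plant species act like fecundity differences and
    are excluded from home/away survival contrasts, which would otherwise
    carry a mechanical fitness imprint unrelated to the soil community.
    ``include_fitness=True`` multiplies rows by zeta.
    """
    state = sim.state if state is None else state
    theta_m, theta_p = sim.theta_fields(state)
    p = sim.params
    zeta = p.zeta[None, :] if include_fitness else 1.0
    scores = recruitment_mod.survival_score(
        theta_m, theta_p, zeta, p.g, p.h, literal_logistic=p.literal_logistic
    )
    k = p.k
    S = np.full((k, k), np.nan)
    for A in range(k):
        mask = state.species == A
        if mask.any():
            S[:, A] = scores[mask].mean(axis=0)
    return SurvivalMatrix(S=S)


def interaction_coefficient(S: SurvivalMatrix | np.ndarray, A: int, B: int) -> float:
    """Pairwise feedback I_s for adult/seedling species pair (A, B)."""
    if A == B:
        raise ValueError("I_s is defined for distinct species pairs")
    M = S.S if isinstance(S, SurvivalMatrix) else np.asarray(S, dtype=float)
    value = M[A, A] + M[B, B] - (M[A, B] + M[B, A])
    if np.isnan(value):
        raise ValueError(f"species pair ({A}, {B}) includes an absent species")
    return float(value)


def abundance_psf_correlation(focal_Is: np.ndarray, abundances: np.ndarray) -> float:
    """Spearman rank correlation between focal feedback and host abundance.

    NaN when either vector is constant (correlation undefined).
    """
    focal_Is = np.asarray(focal_Is, dtype=float)
    abundances = np.asarray(abundances, dtype=float)
    ok = ~np.isnan(focal_Is)
    if ok.sum() < 3:
        return float("nan")
    if np.ptp(focal_Is[ok]) == 0 or np.ptp(abundances[ok]) == 0:
        return float("nan")
    rho = stats.spearmanr(focal_Is[ok], abundances[ok]).statistic
    return float(rho)


def feedback_report(S: SurvivalMatrix, abundances: np.ndarray) -> FeedbackReport:
    """All pairwise I_s plus focal means, extrema, rho, and spread."""
    k = S.k
    pairwise = np.full((k, k), np.nan)
    for A in range(k):
        for B in range(A + 1, k):
            if not np.isnan(S.S[[A, B]][:, [A, B]]).any():
                val = interaction_coefficient(S, A, B)
                pairwise[A, B] = pairwise[B, A] = val
    with np.errstate(invalid="ignore"):
        focal = np.array([
            np.nanmean(pairwise[a]) if not np.isnan(pairwise[a]).all() else np.nan
            for a in range(k)
        ])
    defined = pairwise[~np.isnan(pairwise)]
    I_max = float(defined.max()) if defined.size else float("nan")
    I_min = float(defined.min()) if defined.size else float("nan")
    rho = abundance_psf_correlation(focal, abundances)
    ok = ~np.isnan(focal)
    sigma = float(np.std(focal[ok], ddof=1)) if ok.sum() > 1 else float("nan")
    return FeedbackReport(
        survival=S, pairwise_Is=pairwise, focal_Is=focal,
        I_max=I_max, I_min=I_min, rho=rho, sigma_Is=sigma,
    )


def measure_initial_psf(
    params: ParameterSet,
    seed: int | None = None,
    steps: int = INITIAL_PSF_STEPS,
) -> FeedbackReport:
    """Feedback after microbiomes equilibrate on their hosts without mortality.

    Builds a fresh lattice and runs ``steps`` time steps with no host
    replacement (microbial competition and propagule immigration only),
    then measures the survival matrix at every cell.  This is the
    feedback value used as a predictor of run outcomes.
    """
    sim = Simulation(params, seed=seed)
    sim.settle(steps)
    S = survival_matrix(sim)
    return feedback_report(S, sim.state.abundances(params.k))


def measure_end_psf(
    sim: Simulation,
    abundances: np.ndarray,
    settle_steps: int = INITIAL_PSF_STEPS,
) -> FeedbackReport:
    """End-of-run feedback, measured with the same settling protocol.

    Continues the simulation ``settle_steps`` further steps without host
    mortality so the survival fields reflect the standing plant
    community rather than a single noisy snapshot, then computes all
    pairwise I_s.  ``abundances`` (typically the final pre-settling
    abundances) are used for the abundance–feedback correlation.
    The simulation state is advanced in place.
    """
    sim.settle(settle_steps)
    return feedback_report(survival_matrix(sim), abundances)


def equilibrium_metric(
    series: np.ndarray,
    window: int = 600,
    thin: int = 10,
    change_span: int = 100,
) -> float:
    """Equilibrium metric P_e for the most-common-species abundance series.

    The final ``window`` steps are thinned to every ``thin``-th value;
    abundance changes are taken over disjoint ``change_span``-step
    windows of that tail whose endpoints are also distinct (five of them
    at the defaults); P_e is the p-value of a two-sided one-sample
    t-test of those changes against zero.  Sharing no samples keeps the
    changes independent under a stationary series, so the t-test is
    calibrated: P_e is uniform on [0, 1] at equilibrium.  (Overlapping
    or endpoint-sharing windows would correlate the changes and
    concentrate P_e away from uniformity.)  High P_e means no detectable
    drift.  A perfectly constant series returns 1; a series with a
    deterministic nonzero trend returns 0.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[0] < window + 1:
        raise ValueError(f"series must cover at least {window} steps")
    tail = series[-(window + 1):]
    thinned = tail[::thin]
    lag = change_span // thin
    starts = np.arange(0, thinned.shape[0] - lag, lag + 1)
    changes = thinned[starts + lag] - thinned[starts]
    if np.ptp(changes) == 0:
        return 1.0 if changes[0] == 0 else 0.0
    return float(stats.ttest_1samp(changes, 0.0).pvalue)


def equilibrium_from_trajectory(traj: Trajectory) -> float:
    """P_e of the species most common at the end of the run."""
    most_common = int(np.argmax(traj.abundance[-1]))
    return equilibrium_metric(traj.abundance[:, most_common])


def heterospecific_fraction(state: LatticeState | np.ndarray) -> float:
    """Mean fraction of each tree's two circular neighbours of another species.

    0 for a monoculture; 1 when no two adjacent trees share a species.
    """
    species = state.species if isinstance(state, LatticeState) else np.asarray(state)
    left = species != np.roll(species, 1)
    right = species != np.roll(species, -1)
    return float((left.astype(float) + right.astype(float)).mean() / 2.0)


def summarize_run(
    sim: Simulation,
    traj: Trajectory,
    initial: FeedbackReport | None = None,
    presence_threshold: float = MICROBE_PRESENCE_THRESHOLD,
) -> dict:
    """Per-run summary metrics used by sweeps and outcome classification."""
    k = sim.params.k
    final_ab = traj.abundance[-1]
    # Richness and spatial structure are censused before the settling
    # steps of the feedback measurement advance the state.
    mut_richness = int((sim.state.mutualists.sum(axis=0) > presence_threshold).sum())
    path_richness = int((sim.state.pathogens.sum(axis=0) > presence_threshold).sum())
    hetero = heterospecific_fraction(sim.state)
    end = measure_end_psf(sim, final_ab)
    out = {
        "plant_richness": int((final_ab > 0).sum()),
        "mutualist_richness": mut_richness,
        "pathogen_richness": path_richness,
        "rho": end.rho,
        "sigma_Is": end.sigma_Is,
        "I_max_end": end.I_max,
        "I_min_end": end.I_min,
        "heterospecific_fraction": hetero,
        "P_e": (
            equilibrium_from_trajectory(traj)
            if traj.abundance.shape[0] >= 601 else float("nan")
        ),
    }
    for j in range(k):
        out[f"abundance_{j}"] = int(final_ab[j])
        out[f"focal_Is_{j}"] = float(end.focal_Is[j])
    if initial is not None:
        out["I_max_initial"] = initial.I_max
        out["I_min_initial"] = initial.I_min
    return out
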