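"""Random-forest outcome characterization and surrogate-guided PSO.

Sweep output is summarized with random-forest classifiers: which traits
predict coexistence, strong negative feedback, or a positive
abundance–feedback correlation.  Importance is permutation importance
(mean decrease in accuracy normalized by its standard deviation) and
per-sample feature contributions follow the decision-path attribution of
forestFloor/treeinterpreter: walking each tree from root to leaf, the
change in predicted class probability at every split is credited to the
split feature.

The particle swarm explores trait space under a random-forest surrogate:
at each step the forest is retrained on all archived runs, its ten most
promising parameterizations form the elite pool, and each particle is
attracted toward a randomly chosen elite member::

    v <- w * v + c * rand * (p - x),    x <- x + v

with inertia w = 0.5 and attraction c = 0.8.  Four random particles are
re-randomized each step to limit premature convergence, and the
hierarchical variant halves the number of independent swarms stage by
stage (16 -> 8 -> 4 -> 2 -> 1), pooling archives as swarms merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.metrics import accuracy_score, precision_score, recall_score

from .parameters import PARAMETER_NAMES, parameter_bounds

__all__ = [
    "ForestReport",
    "SwarmState",
    "fit_outcome_forest",
    "feature_contributions",
    "pso_velocity_update",
    "hierarchical_pso",
]

PSO_INERTIA = 0.5
PSO_ATTRACTION = 0.8
ELITE_POOL_SIZE = 10
N_RERANDOMIZED = 4

LABELS = ("coexistence", "strong_negative_feedback", "abundance_correlation")


@dataclass
class ForestReport:
    label: str
    features: list[str]
    model: RandomForestClassifier
    accuracy: float
    precision: float
    recall: float
    importance: pd.DataFrame           # parameter, importance, sd, normalized
    contributions: pd.DataFrame | None  # sample x parameter additive terms
    n_per_class: int


def _balance(X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Downsample the majority class so both classes are equally represented."""
    pos = np.flatnonzero(y)
    neg = np.flatnonzero(~y)
    m = min(pos.size, neg.size)
    idx = np.concatenate([
        rng.choice(pos, size=m, replace=False),
        rng.choice(neg, size=m, replace=False),
    ])
    rng.shuffle(idx)
    return X[idx], y[idx]


def fit_outcome_forest(
    records: pd.DataFrame,
    label: str,
    include_Imax: bool | None = None,
    rng: np.random.Generator | None = None,
    with_contributions: bool = True,
    n_estimators: int = 500,
) -> ForestReport:
    """Train a balanced random-forest classifier for one outcome label.

    Features are the sampled traits; initial I_max is added as a
    predictor only for the coexistence label (its default).  Accuracy,
    precision, and recall are computed from out-of-bag votes on the
    balanced sample, and importance is permutation importance normalized
    by its standard deviation.
    """
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}")
    rng = np.random.default_rng(0) if rng is None else rng
    if include_Imax is None:
        include_Imax = label == "coexistence"
    features = list(PARAMETER_NAMES)
    if include_Imax:
        features.append("I_max_initial")
    data = records.dropna(subset=features)
    X = data[features].to_numpy(dtype=float)
    y = data[label].to_numpy(dtype=bool)
    if y.all() or not y.any():
        raise ValueError(f"label {label!r} has a single class; cannot fit")
    Xb, yb = _balance(X, y, rng)
    model = RandomForestClassifier(
        n_estimators=n_estimators,
        oob_score=True,
        random_state=int(rng.integers(0, 2**31 - 1)),
        n_jobs=1,
    )
    model.fit(Xb, yb)
    oob_pred = model.oob_decision_function_[:, list(model.classes_).index(True)] > 0.5
    acc = accuracy_score(yb, oob_pred)
    prec = precision_score(yb, oob_pred, zero_division=0.0)
    rec = recall_score(yb, oob_pred, zero_division=0.0)
    perm = permutation_importance(
        model, Xb, yb, n_repeats=10,
        random_state=int(rng.integers(0, 2**31 - 1)), n_jobs=1,
    )
    importance = pd.DataFrame({
        "parameter": features,
        "importance": perm.importances_mean,
        "sd": perm.importances_std,
    })
    with np.errstate(divide="ignore", invalid="ignore"):
        importance["normalized"] = np.where(
            importance["sd"] > 0,
            importance["importance"] / importance["sd"],
            0.0,
        )
    contrib = feature_contributions(model, Xb, features) if with_contributions else None
    return ForestReport(
        label=label, features=features, model=model,
        accuracy=float(acc), precision=float(prec), recall=float(rec),
        importance=importance, contributions=contrib,
        n_per_class=int(yb.sum()),
    )


def feature_contributions(
    model: RandomForestClassifier,
    X: np.ndarray,
    feature_names: Sequence[str],
) -> pd.DataFrame:
    """Per-sample additive feature contributions to P(positive class).

    For each tree and sample, the difference in the node-mean positive
    probability across each split on the root-to-leaf path is credited to
    the split feature; contributions are averaged over trees.  The
    prediction decomposes as bias + sum of contributions.
    """
    X = np.asarray(X, dtype=float)
    pos = list(model.classes_).index(True)
    total = np.zeros((X.shape[0], len(feature_names)))
    bias = 0.0
    for est in model.estimators_:
        tree = est.tree_
        values = tree.value[:, 0, :]
        probs = values[:, pos] / values.sum(axis=1)
        node_indicator = est.decision_path(X)
        indptr, indices = node_indicator.indptr, node_indicator.indices
        bias += probs[0]
        for i in range(X.shape[0]):
            path = indices[indptr[i]:indptr[i + 1]]
            for parent, child in zip(path[:-1], path[1:]):
                total[i, tree.feature[parent]] += probs[child] - probs[parent]
    n_trees = len(model.estimators_)
    df = pd.DataFrame(total / n_trees, columns=list(feature_names))
    df.attrs["bias"] = bias / n_trees
    return df


# ----------------------------------------------------------------------
# Particle swarm optimization
# ----------------------------------------------------------------------

@dataclass
class SwarmState:
    positions: np.ndarray            # (particles, dims)
    velocities: np.ndarray           # (particles, dims)
    elite_pool: np.ndarray           # (<=10, dims)
    w: float = PSO_INERTIA
    c: float = PSO_ATTRACTION
    bounds: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.bounds is None:
            self.bounds = parameter_bounds()
        if self.elite_pool.shape[0] > ELITE_POOL_SIZE:
            raise ValueError("elite pool exceeds 10 solutions")


def random_positions(n: int, rng: np.random.Generator,
                     bounds: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    lows, highs = parameter_bounds() if bounds is None else bounds
    return rng.uniform(lows, highs, size=(n, lows.size))


def pso_velocity_update(
    swarm: SwarmState,
    rng: np.random.Generator,
    n_rerandomized: int = N_RERANDOMIZED,
) -> SwarmState:
    """One PSO step: velocity + position update, clipping, re-randomization.

    Each particle is attracted toward an elite solution drawn uniformly
    from the pool, with a fresh uniform random factor per particle and
    dimension.  Positions are clipped to trait bounds (velocity zeroed in
    clipped dimensions) and ``n_rerandomized`` random particles are reset
    to fresh uniform positions with zero velocity.
    """
    if swarm.elite_pool.shape[0] == 0:
        raise ValueError("elite pool is empty")
    n, d = swarm.positions.shape
    lows, highs = swarm.bounds
    targets = swarm.elite_pool[rng.integers(0, swarm.elite_pool.shape[0], size=n)]
    rand = rng.random((n, d))
    v = swarm.w * swarm.velocities + swarm.c * rand * (targets - swarm.positions)
    x = swarm.positions + v
    clipped_low, clipped_high = x < lows, x > highs
    x = np.clip(x, lows, highs)
    v = np.where(clipped_low | clipped_high, 0.0, v)
    if n_rerandomized:
        reset = rng.choice(n, size=min(n_rerandomized, n), replace=False)
        x[reset] = random_positions(reset.size, rng, swarm.bounds)
        v[reset] = 0.0
    return SwarmState(positions=x, velocities=v, elite_pool=swarm.elite_pool,
                      w=swarm.w, c=swarm.c, bounds=swarm.bounds)


def _surrogate_elites(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    n_estimators: int,
) -> tuple[np.ndarray, RandomForestClassifier | None]:
    """Fit the RF surrogate on the archive, return its top-10 archived points.

    With a single-class archive no forest can be fit; the elites fall
    back to random archived points (positives first if any exist).
    """
    if y.any() and not y.all():
        model = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=int(rng.integers(0, 2**31 - 1)), n_jobs=1,
        )
        model.fit(X, y)
        scores = model.predict_proba(X)[:, list(model.classes_).index(True)]
        order = np.argsort(-scores, kind="stable")
        return X[order[:ELITE_POOL_SIZE]].copy(), model
    pool_idx = rng.choice(X.shape[0], size=min(ELITE_POOL_SIZE, X.shape[0]), replace=False)
    return X[pool_idx].copy(), None


@dataclass
class PSOResult:
    best: np.ndarray                 # best parameter vector
    best_score: float                # surrogate probability of the target label
    archive: pd.DataFrame            # every evaluated run: parameters + label
    feature_names: list[str] = field(default_factory=lambda: list(PARAMETER_NAMES))


def hierarchical_pso(
    objective: Callable[[np.ndarray], bool],
    rng: np.random.Generator,
    n_swarms: int = 16,
    particles: int = 50,
    steps_per_stage: int = 20,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    surrogate_estimators: int = 200,
) -> PSOResult:
    """Stage-wise halving PSO with a random-forest surrogate.

    ``objective`` maps a parameter vector to the boolean target label
    (in production: whether a simulation run satisfies the
    coexistence-with-positive-correlation criterion).  Each stage runs
    independent swarms for ``steps_per_stage`` steps; at every step the
    surrogate is retrained on the swarm's full archive and its ten most
    promising evaluated parameterizations form the elite pool.  Stages
    halve the swarm count, merging archives, until a single swarm
    remains; the final forest picks the most promising parameterization
    among all evaluated runs.  Objective failures mark the particle's
    label False and the particle is re-randomized next step.
    """
    bounds = parameter_bounds() if bounds is None else bounds
    dims = bounds[0].size

    def evaluate(positions: np.ndarray) -> np.ndarray:
        out = np.zeros(positions.shape[0], dtype=bool)
        for i, x in enumerate(positions):
            try:
                out[i] = bool(objective(x))
            except Exception:
                out[i] = False
        return out

    # One archive (X, y) per active swarm; merged when swarms halve.
    archives: list[tuple[list[np.ndarray], list[np.ndarray]]] = []
    swarm_positions = []
    for _ in range(n_swarms):
        pos = random_positions(particles, rng, bounds)
        y = evaluate(pos)
        archives.append(([pos], [y]))
        swarm_positions.append((pos, np.zeros_like(pos)))

    while True:
        for s in range(len(archives)):
            X_arch = np.concatenate(archives[s][0])
            y_arch = np.concatenate(archives[s][1])
            pos, vel = swarm_positions[s]
            for _ in range(steps_per_stage):
                elites, _model = _surrogate_elites(X_arch, y_arch, rng, surrogate_estimators)
                swarm = SwarmState(positions=pos, velocities=vel,
                                   elite_pool=elites, bounds=bounds)
                swarm = pso_velocity_update(swarm, rng)
                pos, vel = swarm.positions, swarm.velocities
                y_new = evaluate(pos)
                X_arch = np.concatenate([X_arch, pos])
                y_arch = np.concatenate([y_arch, y_new])
            archives[s] = ([X_arch], [y_arch])
            swarm_positions[s] = (pos, vel)
        if len(archives) == 1:
            break
        # Halve: merge archive pairs; each merged swarm restarts from the
        # first member's particles.
        merged_arch, merged_swarms = [], []
        for a in range(0, len(archives) - 1, 2):
            merged_arch.append((
                archives[a][0] + archives[a + 1][0],
                archives[a][1] + archives[a + 1][1],
            ))
            merged_swarms.append(swarm_positions[a])
        if len(archives) % 2:
            merged_arch.append(archives[-1])
            merged_swarms.append(swarm_positions[-1])
        archives, swarm_positions = merged_arch, merged_swarms

    X_all = np.concatenate(archives[0][0])
    y_all = np.concatenate(archives[0][1])
    elites, model = _surrogate_elites(X_all, y_all, rng, surrogate_estimators)
    if model is not None:
        scores = model.predict_proba(X_all)[:, list(model.classes_).index(True)]
    else:
        scores = y_all.astype(float)
    best_idx = int(np.argmax(scores))
    archive = pd.DataFrame(X_all, columns=list(PARAMETER_NAMES)[:dims] if dims == len(PARAMETER_NAMES) else [f"x{i}" for i in range(dims)])
    archive["label"] = y_all
    archive["surrogate_score"] = scores
    return PSOResult(
        best=X_all[best_idx].copy(),
        best_score=float(scores[best_idx]),
        archive=archive,
        feature_names=list(archive.columns[:-2]),
    )
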