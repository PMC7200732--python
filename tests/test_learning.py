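import numpy as np
import pandas as pd
import pytest

from psfsim.learning import (
    SwarmState,
    feature_contributions,
    fit_outcome_forest,
    hierarchical_pso,
    pso_velocity_update,
    random_positions,
)
from psfsim.parameters import PARAMETER_NAMES, TRAIT_BOUNDS, parameter_bounds


def synthetic_records(n, rng, label_fn, label="strong_negative_feedback"):
    """Records table with uniform random parameters and a planted label."""
    lows, highs = parameter_bounds()
    X = rng.uniform(lows, highs, size=(n, lows.size))
    df = pd.DataFrame(X, columns=list(PARAMETER_NAMES))
    df["I_max_initial"] = rng.uniform(-2, 1, n)
    df[label] = label_fn(df)
    return df


class TestOutcomeForest:
    def test_planted_signal_recovery(self, rng):
        """A label that is a deterministic function of s_p must rank s_p
        first in permutation importance and classify accurately."""
        df = synthetic_records(600, rng, lambda d: d["s_p"] < 0.5)
        report = fit_outcome_forest(df, "strong_negative_feedback", rng=rng,
                                    with_contributions=False, n_estimators=200)
        assert report.accuracy > 0.9
        top = report.importance.sort_values("importance", ascending=False)
        assert top.iloc[0]["parameter"] == "s_p"

    def test_label_independent_parameter_has_null_importance(self, rng):
        df = synthetic_records(600, rng, lambda d: d["s_p"] < 0.5)
        report = fit_outcome_forest(df, "strong_negative_feedback", rng=rng,
                                    with_contributions=False, n_estimators=200)
        imp = report.importance.set_index("parameter")
        # a trait with no relation to the label: importance within noise of 0
        assert imp.loc["r_m", "importance"] < 5 * max(imp.loc["r_m", "sd"], 1e-9)
        assert imp.loc["s_p", "importance"] > 10 * imp.loc["r_m", "importance"]

    def test_permuted_labels_are_chance_level(self, rng):
        df = synthetic_records(400, rng, lambda d: d["s_p"] < 0.5)
        df["strong_negative_feedback"] = rng.permutation(
            df["strong_negative_feedback"].to_numpy()
        )
        report = fit_outcome_forest(df, "strong_negative_feedback", rng=rng,
                                    with_contributions=False, n_estimators=200)
        assert abs(report.accuracy - 0.5) < 0.12

    def test_imax_included_only_for_coexistence(self, rng):
        df = synthetic_records(200, rng, lambda d: d["g"] > 10, label="coexistence")
        rep_coex = fit_outcome_forest(df, "coexistence", rng=rng,
                                      with_contributions=False, n_estimators=50)
        assert "I_max_initial" in rep_coex.features
        df2 = synthetic_records(200, rng, lambda d: d["g"] > 10)
        rep_neg = fit_outcome_forest(df2, "strong_negative_feedback", rng=rng,
                                     with_contributions=False, n_estimators=50)
        assert "I_max_initial" not in rep_neg.features

    def test_single_class_rejected(self, rng):
        df = synthetic_records(50, rng, lambda d: np.ones(len(d), dtype=bool))
        with pytest.raises(ValueError):
            fit_outcome_forest(df, "strong_negative_feedback", rng=rng)

    def test_contributions_decompose_prediction(self, rng):
        """Decision-path attribution identity: bias + sum of per-feature
        contributions equals the forest's predicted probability."""
        df = synthetic_records(150, rng, lambda d: d["h"] > 0.85)
        report = fit_outcome_forest(df, "strong_negative_feedback", rng=rng,
                                    n_estimators=60)
        contrib = report.contributions
        X = df.dropna(subset=report.features)
        # contributions were computed on the balanced sample inside the fit;
        # recompute on a fresh matrix to test the identity directly
        Xm = X[report.features].to_numpy()[:40]
        c = feature_contributions(report.model, Xm, report.features)
        pos = list(report.model.classes_).index(True)
        pred = report.model.predict_proba(Xm)[:, pos]
        total = c.attrs["bias"] + c.to_numpy().sum(axis=1)
        assert np.allclose(total, pred, atol=1e-10)
        assert contrib.shape[1] == len(report.features)


class FakeRng:
    """Deterministic stand-in for Generator in arithmetic tests."""

    def __init__(self, rand_value=0.5, elite_index=0):
        self.rand_value = rand_value
        self.elite_index = elite_index

    def random(self, size=None):
        return np.full(size, self.rand_value) if size is not None else self.rand_value

    def integers(self, low, high=None, size=None):
        return np.full(size, self.elite_index, dtype=int)

    def choice(self, n, size=None, replace=True):
        return np.arange(size)

    def uniform(self, lo, hi, size=None):
        return np.broadcast_to((np.asarray(lo) + np.asarray(hi)) / 2, size).copy()


class TestPsoUpdate:
    def test_velocity_position_arithmetic(self):
        """v' = 0.5*1 + 0.8*0.5*(4-2) = 1.3; x' = 2 + 1.3 = 3.3."""
        bounds = (np.array([-10.0]), np.array([10.0]))
        swarm = SwarmState(
            positions=np.array([[2.0]]),
            velocities=np.array([[1.0]]),
            elite_pool=np.array([[4.0]]),
            bounds=bounds,
        )
        out = pso_velocity_update(swarm, FakeRng(0.5), n_rerandomized=0)
        assert out.velocities[0, 0] == pytest.approx(1.3)
        assert out.positions[0, 0] == pytest.approx(3.3)

    def test_particle_at_elite_with_zero_velocity_is_stationary(self):
        bounds = (np.array([0.0, 0.0]), np.array([1.0, 1.0]))
        x = np.array([[0.4, 0.6]])
        swarm = SwarmState(positions=x.copy(), velocities=np.zeros((1, 2)),
                           elite_pool=x.copy(), bounds=bounds)
        out = pso_velocity_update(swarm, FakeRng(0.9), n_rerandomized=0)
        assert np.allclose(out.positions, x)
        assert np.allclose(out.velocities, 0.0)

    def test_clipping_zeroes_velocity(self):
        bounds = (np.array([0.0]), np.array([1.0]))
        swarm = SwarmState(positions=np.array([[0.95]]),
                           velocities=np.array([[0.5]]),
                           elite_pool=np.array([[5.0]]),  # pulls out of bounds
                           bounds=bounds)
        out = pso_velocity_update(swarm, FakeRng(1.0), n_rerandomized=0)
        assert out.positions[0, 0] == 1.0
        assert out.velocities[0, 0] == 0.0

    def test_rerandomized_particles_reset(self, rng):
        lows, highs = parameter_bounds()
        n = 12
        x = random_positions(n, rng)
        swarm = SwarmState(positions=x.copy(), velocities=np.zeros_like(x),
                           elite_pool=x[:1].copy())
        out = pso_velocity_update(swarm, np.random.default_rng(0))
        # with a single elite equal to particle 0, most particles converge
        # toward it but exactly 4 are re-randomized
        assert np.all(out.positions >= lows) and np.all(out.positions <= highs)

    def test_bounds_respected_over_many_steps(self):
        rng = np.random.default_rng(4)
        lows, highs = parameter_bounds()
        x = random_positions(30, rng)
        swarm = SwarmState(positions=x, velocities=np.zeros_like(x),
                           elite_pool=random_positions(5, rng))
        for _ in range(25):
            swarm = pso_velocity_update(swarm, rng)
            assert np.all(swarm.positions >= lows - 1e-12)
            assert np.all(swarm.positions <= highs + 1e-12)

    def test_elite_pool_capped_at_ten(self):
        with pytest.raises(ValueError):
            SwarmState(positions=np.zeros((2, 3)), velocities=np.zeros((2, 3)),
                       elite_pool=np.zeros((11, 3)),
                       bounds=(np.zeros(3), np.ones(3)))


class TestHierarchicalPso:
    def test_planted_basin_recovery(self):
        """Two-parameter toy objective with a known basin: the search must
        land within 5% of the bounds range of the optimum."""
        bounds = (np.zeros(2), np.ones(2))
        center = np.array([0.62, 0.31])

        def objective(x):
            return bool(np.all(np.abs(x - center) < 0.12))

        rng = np.random.default_rng(17)
        result = hierarchical_pso(objective, rng, n_swarms=2, particles=16,
                                  steps_per_stage=6, bounds=bounds,
                                  surrogate_estimators=100)
        assert np.all(np.abs(result.best - center) < 0.12 + 0.05)
        # the search enriches the basin relative to uniform sampling
        hit_rate = result.archive["label"].mean()
        assert hit_rate > (2 * 0.12) ** 2  # uniform expectation ~ 5.8%

    def test_archive_bookkeeping(self):
        bounds = (np.zeros(2), np.ones(2))
        rng = np.random.default_rng(3)
        result = hierarchical_pso(lambda x: x[0] > 0.5, rng, n_swarms=2,
                                  particles=5, steps_per_stage=3, bounds=bounds,
                                  surrogate_estimators=20)
        # stage 1: 2 swarms x (5 initial + 3*5 evaluated); stage 2 (merged):
        # + 3*5 more
        assert len(result.archive) == 2 * (5 + 15) + 15

    def test_single_swarm_reduces_to_plain_pso(self):
        bounds = (np.zeros(1), np.ones(1))
        rng = np.random.default_rng(5)
        result = hierarchical_pso(lambda x: x[0] > 0.8, rng, n_swarms=1,
                                  particles=6, steps_per_stage=4, bounds=bounds,
                                  surrogate_estimators=20)
        assert len(result.archive) == 6 + 4 * 6
        assert result.best.shape == (1,)
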