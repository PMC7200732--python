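import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psfsim.dispersal import build_kernel
from psfsim.microbes import (
    compatibility_matrix,
    competition_rhs,
    competition_step,
    effect_theta,
    immigrate,
)

from conftest import make_guild


def logistic_solution(f0, r, t, K=1.0):
    """Closed-form logistic trajectory with carrying capacity K."""
    return K * f0 * np.exp(r * t) / (K + f0 * (np.exp(r * t) - 1.0))


class TestCompatibility:
    @pytest.mark.parametrize("s", [0.0, 0.03, 0.5, 1.0])
    def test_structure(self, s):
        comp = compatibility_matrix(make_guild(s=s), 4)
        assert np.all(np.diag(comp.e) == 1.0)
        off = comp.e[~np.eye(4, dtype=bool)]
        assert np.all(off == s)

    def test_zero_affinity_power_convention(self):
        """0**q := 0 even for q <= 0: a strict specialist has no growth
        and no competitive effect on non-preferred hosts."""
        comp = compatibility_matrix(make_guild(s=0.0, q=-0.5, c=0.5), 3)
        assert np.all(np.diag(comp.e_q) == 1.0)
        assert np.all(comp.e_q[~np.eye(3, dtype=bool)] == 0.0)
        assert np.all(comp.e_c[~np.eye(3, dtype=bool)] == 0.0)

    def test_generalist_scaled_powers_are_one(self):
        comp = compatibility_matrix(make_guild(s=1.0, q=1.7, c=0.9), 3)
        assert np.all(comp.e_q == 1.0)
        assert np.all(comp.e_c == 1.0)


class TestImmigrate:
    def test_gamma_zero_identity(self):
        field = np.random.default_rng(0).uniform(0, 1, (10, 3))
        out = immigrate(field, build_kernel(2.5, 10), 0.0)
        assert np.allclose(out, field)

    def test_uniform_field_invariant_under_conservative_mode(self):
        """With the dispersed fraction leaving its source, a spatially
        uniform field is a fixed point of dispersal."""
        field = np.full((12, 2), 0.7)
        out = immigrate(field, build_kernel(2.2, 12), 0.3)
        assert np.allclose(out, field, atol=1e-12)

    def test_conservative_mode_conserves_lattice_total(self, rng):
        field = rng.uniform(0, 1, (20, 4))
        out = immigrate(field, build_kernel(2.8, 20), 0.4)
        assert np.allclose(out.sum(axis=0), field.sum(axis=0), rtol=1e-10)
        assert np.all(out >= 0)

    def test_additive_mode_adds_gamma_times_total(self):
        """The arrivals-only variant: a single occupied cell with total
        abundance A adds exactly gamma*A across the lattice."""
        field = np.zeros((9, 1))
        field[4, 0] = 2.0
        out = immigrate(field, build_kernel(2.5, 9), 0.25, mode="additive")
        assert np.all(out >= field)  # never decreases any entry
        assert out.sum() == pytest.approx(2.0 + 0.25 * 2.0)

    def test_uniform_field_scales_under_additive_mode(self):
        field = np.full((8, 2), 0.5)
        out = immigrate(field, build_kernel(2.5, 8), 0.2, mode="additive")
        assert np.allclose(out, 0.6, atol=1e-12)

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            immigrate(np.ones((5, 1)), build_kernel(2.5, 5), 1.0)


class TestEffectTheta:
    def test_zero_community(self):
        assert effect_theta(np.zeros(3), np.ones(3)) == 0.0

    def test_single_taxon_preferred(self):
        assert effect_theta([0.0, 0.7, 0.0], [0.03, 1.0, 0.03]) == pytest.approx(0.7)

    def test_dot_product_with_table_pathogen_affinity(self):
        assert effect_theta([0.5, 0.2], [1.0, 0.03]) == pytest.approx(0.506)

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            effect_theta([-0.1, 0.2], [1.0, 1.0])


class TestCompetitionStep:
    def test_logistic_closed_form(self):
        """Single taxon on its preferred host follows plain logistic growth."""
        traits = make_guild(r=1.0)
        comp = compatibility_matrix(traits, 1)
        F = np.array([[0.1]])
        out = competition_step(F, np.array([0]), traits, comp, dt=1.0)
        assert out[0, 0] == pytest.approx(logistic_solution(0.1, 1.0, 1.0), rel=1e-4)
        assert out[0, 0] == pytest.approx(0.23200, abs=5e-5)

    @pytest.mark.parametrize("r", [0.1, 1.0, 2.0])
    def test_logistic_many_steps(self, r):
        traits = make_guild(r=r)
        comp = compatibility_matrix(traits, 1)
        F = np.array([[0.05]])
        for t in range(1, 6):
            F = competition_step(F, np.array([0]), traits, comp)
            assert F[0, 0] == pytest.approx(logistic_solution(0.05, r, t), rel=1e-4)

    def test_extinction_absorbing_and_capacity_fixed_point(self):
        traits = make_guild(r=1.5)
        comp = compatibility_matrix(traits, 2)
        F = np.array([[0.0, 1.0]])
        host = np.array([1])
        out = competition_step(F, host, traits, comp)
        assert out[0, 0] == 0.0
        assert out[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_two_taxon_coexistence_equilibrium(self):
        """On the preferred host of taxon 0 with alpha*s^c interactions,
        the nullcline intersection predicts the coexistence point:
        F0 = (1 - a01)/(1 - a01*a10), F1 likewise, where a01 = alpha*e_c[1,0]
        and a10 = alpha*e_c[0,0] from the oracle algebra."""
        traits = make_guild(s=0.5, c=1.0, alpha=0.8, r=1.5, q=0.0)
        comp = compatibility_matrix(traits, 2)
        host = np.array([0])
        a01 = traits.alpha * comp.e_c[1, 0]  # effect of taxon 1 on taxon 0
        a10 = traits.alpha * comp.e_c[0, 0]  # effect of taxon 0 on taxon 1
        expected_F0 = (1 - a01) / (1 - a01 * a10)
        expected_F1 = (1 - a10) / (1 - a01 * a10)
        F = np.array([[0.3, 0.3]])
        for _ in range(300):
            F = competition_step(F, host, traits, comp)
        assert F[0, 0] == pytest.approx(expected_F0, rel=1e-3)
        assert F[0, 1] == pytest.approx(expected_F1, rel=1e-3)

    def test_growth_rate_scaling_on_non_preferred_host(self):
        """Early-time slope of a small population on a non-preferred host
        is r * s**q."""
        traits = make_guild(s=0.4, q=1.5, r=1.2)
        comp = compatibility_matrix(traits, 2)
        host = np.array([1])  # taxon 0 grows on non-preferred host 1
        f0 = 1e-6
        F = np.array([[f0, 0.0]])
        out = competition_step(F, host, traits, comp, dt=0.01)
        measured_rate = np.log(out[0, 0] / f0) / 0.01
        assert measured_rate == pytest.approx(1.2 * 0.4**1.5, rel=1e-3)

    def test_higher_q_slows_decline_on_non_preferred_host(self):
        """With s < 1 fixed and a negative bracket, larger q means slower
        decline of a non-preferred taxon."""
        finals = []
        for q in (0.5, 1.0, 2.0):
            traits = make_guild(s=0.3, q=q, r=1.5, alpha=1.0, c=1.0)
            comp = compatibility_matrix(traits, 2)
            host = np.array([1])
            F = np.array([[0.8, 1.0]])  # taxon 1 resident at capacity
            for _ in range(20):
                F = competition_step(F, host, traits, comp)
            finals.append(F[0, 0])
        assert finals[0] < finals[1] < finals[2]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        s=st.floats(0.0, 1.0),
        q=st.floats(-0.5, 2.0),
        c=st.floats(0.5, 2.0),
        alpha=st.floats(0.5, 1.5),
        r=st.floats(0.1, 2.0),
        seed=st.integers(0, 2**20),
    )
    def test_non_negativity_property(self, s, q, c, alpha, r, seed):
        traits = make_guild(s=s, q=q, c=c, alpha=alpha, r=r)
        comp = compatibility_matrix(traits, 3)
        rng = np.random.default_rng(seed)
        F = rng.uniform(0, 1.5, (4, 3))
        hosts = rng.integers(0, 3, 4)
        for _ in range(5):
            F = competition_step(F, hosts, traits, comp)
        assert np.all(F >= 0)
        assert np.all(np.isfinite(F))

    def test_rhs_vectorization_matches_per_tree(self, rng):
        traits = make_guild(s=0.2, q=1.1, c=1.3, alpha=1.2)
        comp = compatibility_matrix(traits, 4)
        F = rng.uniform(0, 1, (6, 4))
        hosts = rng.integers(0, 4, 6)
        full = competition_rhs(F, hosts, traits, comp)
        for i in range(6):
            row = competition_rhs(F[i : i + 1], hosts[i : i + 1], traits, comp)
            assert np.allclose(full[i], row[0])
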