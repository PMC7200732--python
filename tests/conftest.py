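import numpy as np
import pytest

from psfsim.parameters import GuildTraits, ParameterSet, reference_parameterization


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def reference_params():
    return reference_parameterization()


@pytest.fixture
def small_params():
    """Small, fast lattice with the reference trait values."""
    return reference_parameterization(n=30, steps=50, rng_seed=7)


def make_guild(**kw):
    base = dict(s=0.5, gamma=0.2, b=2.5, r=1.0, alpha=1.0, c=1.0, q=1.0)
    base.update(kw)
    return GuildTraits(**base)


def make_params(**kw):
    base = dict(
        mutualists=make_guild(),
        pathogens=make_guild(),
        b_t=2.5, g=10.0, h=0.5, k=5, n=30, steps=50, rng_seed=0,
    )
    base.update(kw)
    return ParameterSet(**base)
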