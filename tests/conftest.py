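import numpy as np
import pytest

from ratchet import FullParams, TwoClassParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tc_canonical():
    """Rare-clicking two-class instance used across analytic checks."""
    return TwoClassParams(N=200, u=0.03, s_eff=0.1)


@pytest.fixture
def full_rare():
    """Full-model instance in the rare-clicking regime (lam = 0.5)."""
    return FullParams(N=100, U=0.1, s=0.2)


@pytest.fixture
def full_fast():
    """Fast-clicking instance (lam = 3, fittest class barely maintained)."""
    return FullParams(N=100, U=0.15, s=0.05)
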