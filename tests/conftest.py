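import numpy as np
import pytest

from ggfit import GGParams, gg_rng
from ggfit.sann import SANNConfig


@pytest.fixture(scope="session")
def light_sann():
    """Shortened annealing schedule so replicated fits stay affordable."""
    return SANNConfig(max_iter=1500, stop_repeat=300)


@pytest.fixture(scope="session")
def theta_a():
    """First study truth: phi=0.5, mu=0.5, alpha=3."""
    return GGParams(0.5, 0.5, 3.0)


@pytest.fixture(scope="session")
def theta_b():
    """Second study truth: phi=0.4, mu=1.5, alpha=4."""
    return GGParams(0.4, 1.5, 4.0)


@pytest.fixture(scope="session")
def sample_a200(theta_a):
    return gg_rng(200, theta_a, seed=42)


@pytest.fixture(scope="session")
def sample_a20(theta_a):
    return gg_rng(20, theta_a, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
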