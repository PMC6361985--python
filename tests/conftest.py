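import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_influence(rng: np.random.Generator, n: int,
                     self_lo: float = 0.05, self_hi: float = 0.95) -> np.ndarray:
    """A random row-stochastic W with w_ii in [self_lo, self_hi] (so a_ii < 1)."""
    W = np.zeros((n, n))
    for i in range(n):
        w_ii = rng.uniform(self_lo, self_hi)
        if n > 1:
            others = rng.dirichlet(np.ones(n - 1)) * (1 - w_ii)
            W[i] = np.insert(others, i, w_ii)
        else:
            W[i, i] = 1.0
    return W


def random_simplex(rng: np.random.Generator, n: int, m: int,
                   supply: float = 100.0) -> np.ndarray:
    return rng.dirichlet(np.ones(m), size=n) * supply


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
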