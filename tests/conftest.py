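import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def white_noise_10006():
    """One i.i.d. standard-normal series at the canonical benchmark length."""
    return np.random.default_rng(7).standard_normal(10006)


@pytest.fixture(scope="session")
def ar1_series():
    """An AR(1) series with coefficient 0.9, N = 4096, for spectral tests."""
    n = 4096
    eps = np.random.default_rng(1).standard_normal(n + 100)
    x = np.empty(n + 100)
    x[0] = 0.0
    for i in range(1, n + 100):
        x[i] = 0.9 * x[i - 1] + eps[i]
    return x[100:]
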