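import numpy as np
import pytest

import smahp


@pytest.fixture(scope="session")
def small_dataset():
    """One seeded scenario-I style dataset shared by read-only tests."""
    cfg = smahp.SimulationConfig(n=200, p=50, k=100, censor_target=0.25, seed=7)
    return smahp.generate_dataset(cfg)


@pytest.fixture(scope="session")
def aft_toy():
    """Small censored log-normal AFT sample with known coefficients."""
    rng = np.random.default_rng(42)
    n = 300
    X = rng.normal(size=(n, 3))
    logt = 1.2 + 0.8 * X[:, 0] - 0.5 * X[:, 1] + 0.6 * rng.normal(size=n)
    t = np.exp(logt)
    c = rng.exponential(np.exp(2.2), size=n)
    time = np.minimum(t, c)
    delta = (t <= c).astype(int)
    return X, time, delta
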