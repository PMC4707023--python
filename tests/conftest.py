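import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_data(rng):
    """A small regression problem: 30 x 3 features, smooth target."""
    X = rng.uniform(-1, 1, size=(30, 3))
    y = X[:, 0] * X[:, 1] + 0.5 * X[:, 2]
    return X, y
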