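import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_model():
    """2-block planted model on 4 nodes: {a,b} and {c,d}."""
    from cognet.synth import make_planted_precision

    return make_planted_precision(
        ["a", "b", "c", "d"], {"a": 0, "b": 0, "c": 1, "d": 1}, within_strength=0.4
    )


@pytest.fixture
def random_pd_theta(rng):
    """Random well-conditioned 4x4 precision matrix."""
    A = rng.standard_normal((4, 4))
    Theta = A @ A.T + 4 * np.eye(4)
    return Theta
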