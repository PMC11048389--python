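import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def phantom64():
    from srpomb import phantoms

    return phantoms.make_phantom_2d(seed=1, size=64, contrast=0.8)


@pytest.fixture
def trials500():
    from srpomb import phantoms

    return phantoms.make_hyperparameter_trials(500, seed=7)


@pytest.fixture
def demo_net():
    """DAG matching the synthetic trial landscape: h1,h2 -> accuracy,
    h1 -> h3 (redundant copy), h4 isolated."""
    from srpomb import pomb

    return pomb.HyperNet(
        edges=[("h1", "accuracy"), ("h2", "accuracy"), ("h1", "h3")],
        nodes=["h4"], target="accuracy",
    )
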