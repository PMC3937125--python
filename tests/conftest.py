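import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from micffl.circuits import KineticParameters

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def params() -> KineticParameters:
    """Package defaults: dimensionless physiological rates."""
    return KineticParameters()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
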