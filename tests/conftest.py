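import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spindlecheck import RateParameters, default_ptk2_parameters

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ptk2() -> RateParameters:
    """Reference PTK2 parameter set (lambda*S = 0.3, k_minus1 = 24)."""
    return default_ptk2_parameters()


@pytest.fixture
def small_params() -> RateParameters:
    """A small chain for which dense oracles are cheap."""
    return RateParameters(lambda_=0.1, k_minus1=1.0, mu=0.05, N=2, S=5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
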