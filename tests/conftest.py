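import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from slidebulge import ParameterSet

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def param_set() -> ParameterSet:
    """Complete synthetic parameter trio shared across tests."""
    return ParameterSet.synthetic(7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
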