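import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cvdcmap as cm
from cvdcmap.cvd import CVDSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def viridis():
    return cm.fixture("viridis")


@pytest.fixture(scope="session")
def jet():
    return cm.fixture("jet")


@pytest.fixture(scope="session")
def gray():
    return cm.fixture("gray")


@pytest.fixture(scope="session")
def deuter100():
    return CVDSpec("deuteranomaly", 100.0)


@pytest.fixture(scope="session")
def viridis_report(viridis, deuter100):
    """The deuteranomaly-100 maxrange optimization of viridis, run once."""
    return cm.optimize(viridis, deuter100, method="maxrange")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
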