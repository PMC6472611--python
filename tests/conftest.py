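import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repeatable",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repeatable")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_anchors():
    from ppadopt import RatoonAnchors

    return RatoonAnchors()


@pytest.fixture
def default_params():
    from ppadopt import BehavioralParams

    return BehavioralParams()


@pytest.fixture
def baseline_coeffs():
    from ppadopt import calibrate_coefficients

    return calibrate_coefficients().coefficients
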