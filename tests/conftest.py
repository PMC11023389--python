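import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def arm_model():
    from ucmthrow import ArmModel

    return ArmModel()


@pytest.fixture(scope="session")
def unit_arm():
    """Arm with unit-length segments for hand-worked geometry checks."""
    from ucmthrow import ArmModel

    return ArmModel(upper_arm_length=1.0, forearm_length=1.0, hand_length=1.0)


@pytest.fixture
def small_ensemble(rng):
    """A 12-trial ensemble around a fixed posture with isotropic deviations."""
    from ucmthrow import TrialEnsemble

    mean = rng.uniform(-30, 30, size=(10, 7))
    dev = rng.normal(0, 2.0, size=(12, 10, 7))
    return TrialEnsemble(mean + dev)
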