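import pytest
from hypothesis import HealthCheck, settings

from hptaxis import HormoneState, get_preset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design_a():
    """Calibrated brain-amplified preset (n1=1, n3=4, n5=2, n7=2)."""
    return get_preset("design_A")


@pytest.fixture(scope="session")
def design_b():
    """Calibrated thyroid-amplified preset (n1=4, n3=n5=n7=1)."""
    return get_preset("design_B")


@pytest.fixture(scope="session")
def design_a_printed():
    return get_preset("design_A_printed")


@pytest.fixture(scope="session")
def design_b_printed():
    return get_preset("design_B_printed")


@pytest.fixture(scope="session")
def basal():
    """The calibration target state (TRH, TSH, TH) = (1, 1, 15)."""
    return HormoneState(1.0, 1.0, 15.0)
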