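import warnings

import pytest
from hypothesis import HealthCheck, settings

import crabrisk as cr

settings.register_profile(
    "crabrisk",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("crabrisk")


@pytest.fixture(scope="session")
def baseline_table() -> cr.HarvestTable:
    return cr.packaged_baseline()


@pytest.fixture(scope="session")
def uncertain() -> cr.UncertainInputs:
    return cr.UncertainInputs()


@pytest.fixture(scope="session")
def calibrated() -> cr.ScenarioLevels:
    """Scenario levels calibrated from the packaged published losses.

    The packaged calibration legitimately warns that the fitted mussel intake
    is not monotone across calorie levels; tests that need the levels, not the
    warning, use this fixture.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", cr.CalibrationWarning)
        return cr.calibrated_levels()
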