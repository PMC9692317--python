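import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from spicpms import IntensityDistribution, TimeTrace, default_calibration


@pytest.fixture
def worked_sample() -> IntensityDistribution:
    """Three-bin sample histogram traceable fully by hand."""
    return IntensityDistribution({0: 5, 1: 3, 2: 2}, n=10, dwell_time=10.0)


@pytest.fixture
def worked_blank() -> IntensityDistribution:
    return IntensityDistribution({0: 6, 1: 4}, n=10, dwell_time=10.0)


@pytest.fixture
def small_trace() -> TimeTrace:
    return TimeTrace(counts=np.array([3, 5, 3, 0]), dwell_time=10.0)


@pytest.fixture
def reference_calibration():
    """Reference millisecond setup: 5.7% transport efficiency, 0.28 mL/min,
    1 count per 71 nm TiO2 particle."""
    return default_calibration()
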