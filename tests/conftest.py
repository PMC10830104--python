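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

from rhizosense.calibration import CalibrationCurve
from rhizosense.trace_io import ExperimentRecord, TimeSeries


@pytest.fixture
def curve():
    """Log-log calibration with slope -0.5, 1.6 kOhm at 1 M."""
    return CalibrationCurve(
        salt_name="KNO3", slope=-0.5, intercept=3.2, c_min=1e-8, c_max=0.1,
        fit_r2=1.0, n_points=15,
    )


@pytest.fixture
def impedance_record():
    times = np.arange(0.0, 4 * 3600.0, 60.0)
    values = np.full_like(times, 2.0e4)
    ts = TimeSeries(times, values, "impedance")
    return ExperimentRecord(
        trace=ts,
        salt_name="KNO3",
        addition_time=3 * 3600.0,
        addition_volume_ul=30.0,
        addition_concentration=0.1,
        n_plants=30,
        plant_age_days=9,
    )
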