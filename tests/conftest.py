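import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import respitex as rx

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def calibration_points():
    return rx.default_calibration_points()


@pytest.fixture(scope="session")
def gauge_response(calibration_points):
    return rx.fit_gauge_response(calibration_points, rx.DEFAULT_R0_KOHM)


@pytest.fixture()
def hold_trace():
    """Factory for a constant-elongation strain trace."""

    def make(elongation_mm: float, duration: float = 5.0, dt: float = 0.05):
        t = np.arange(int(round(duration / dt)) + 1) * dt
        return rx.StrainTrace(
            t=t, elongation=np.full_like(t, elongation_mm), dt=dt
        )

    return make
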