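import pytest

from leafscan.experiments import calibrated_camera
from leafscan.geometry import CameraModel, default_camera


@pytest.fixture(scope="session")
def bench_camera() -> CameraModel:
    """Camera with the bench-calibrated power-law constants (a=381, b=-0.95)."""
    return CameraModel()


@pytest.fixture(scope="session")
def geometric_camera() -> CameraModel:
    """Default angular camera model (28 deg half-angle, 640x480)."""
    return default_camera()


@pytest.fixture(scope="session")
def selfcal_camera() -> CameraModel:
    """Camera whose (a, b) are fit from the simulated calibration bench."""
    return calibrated_camera()
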