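import numpy as np
import pytest

from ctcm.device_cycle import CycleParams, default_calibration
from ctcm.synthetic import SceneParams


@pytest.fixture(scope="session")
def cycle():
    """Device defaults: 1.2 Hz, 40% systole, 80 mmHg peak."""
    return CycleParams()


@pytest.fixture(scope="session")
def calibration():
    return default_calibration()


@pytest.fixture(scope="session")
def scene128():
    """Quarter-resolution scene: the 7-mm ring in a 128 px frame."""
    return SceneParams(image_size_px=(128, 128), mm_per_px=8.0 / 128.0)


@pytest.fixture(scope="session")
def scene64():
    return SceneParams(image_size_px=(64, 64), mm_per_px=8.0 / 64.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
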