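import numpy as np
import pytest

from eegdecode import WindowSpec
from eegdecode.validation import load_calibration


@pytest.fixture(scope="session")
def calibration() -> dict:
    return load_calibration()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def window_spec() -> WindowSpec:
    return WindowSpec(width_ms=50.0, step_ms=20.0)


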