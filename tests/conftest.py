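import numpy as np
import pytest

from gaitsole.insole_sim import FsrSensorModel, GaitProfile
from gaitsole.signal_chain import CALIBRATION_RIG, INSOLE


@pytest.fixture
def ideal_fsr_model():
    """Trial-1 FSR ground truth with noise and hysteresis switched off."""
    return FsrSensorModel(hysteresis_factor=0.0, voltage_noise_sd=0.0)


@pytest.fixture
def default_profile():
    return GaitProfile(seed=42)


@pytest.fixture
def rig():
    return CALIBRATION_RIG


@pytest.fixture
def insole_chain():
    return INSOLE


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
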