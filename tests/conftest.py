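import numpy as np
import pytest

from sskit import build_codebook
from sskit.synth import AcquisitionSpec, SSVEPModel


@pytest.fixture(scope="session")
def codebook40():
    """Default 40-target grid: 8.0-15.8 Hz, 0.2 Hz steps, 0.5*pi phase steps."""
    return build_codebook()


@pytest.fixture(scope="session")
def codebook4():
    """Small 4-target codebook for fast session-level tests."""
    return build_codebook(4, 9.0, 1.0, 0.0, 0.5 * np.pi)


@pytest.fixture(scope="session")
def acq():
    """1 kHz, 21-channel 10-20 montage, 0.5-100 Hz band."""
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def noiseless_model():
    return SSVEPModel(snr_db=np.inf)


@pytest.fixture(scope="session")
def flat_model():
    """Single-harmonic, unit-gain, noiseless: analytically exact epochs."""
    return SSVEPModel(snr_db=np.inf, n_harmonics=1, channel_gains=np.ones(21))
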