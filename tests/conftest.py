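import numpy as np
import pytest

from pcgsnr.segmentation import segment_recording
from pcgsnr.simulate import generate_recording


@pytest.fixture(scope="session")
def rec20():
    """30 s paired recording calibrated to 20 dB initial S1 SNR."""
    return generate_recording(30.0, 2000.0, 60.0, target_snr_db=20.0, seed=101)


@pytest.fixture(scope="session")
def seg20(rec20):
    return segment_recording(rec20)


@pytest.fixture(scope="session")
def rec25():
    """60 s clean recording (25 dB) for latency recovery checks."""
    return generate_recording(60.0, 2000.0, 60.0, target_snr_db=25.0, seed=7)


@pytest.fixture(scope="session")
def seg25(rec25):
    return segment_recording(rec25)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
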