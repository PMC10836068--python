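import numpy as np
import pytest

from flimetab.config import AcquisitionConfig


@pytest.fixture(scope="session")
def acq():
    """Default 80 MHz / 256-bin acquisition."""
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def small_acq():
    """16x16 frame acquisition for fast end-to-end tests."""
    return AcquisitionConfig(frame_shape=(16, 16))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
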