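import numpy as np
import pytest

from kindlekit.synthdata import ProtocolConfig


@pytest.fixture
def fast_protocol() -> ProtocolConfig:
    """Protocol with shortened observation windows for quick EEG synthesis.

    Stimulation constants (10 s stimulus, 60 Hz, 2 kHz sampling, 3 channels)
    stay at their defaults; only the PRE/POST windows are reduced.
    """
    return ProtocolConfig(pre_window_s=30.0, post_window_s=60.0, pre_window_test_s=20.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
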