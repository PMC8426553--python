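import numpy as np
import pytest

from attnspeech.audio import Waveform
from attnspeech.features import FrameParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def frame_params():
    return FrameParams()  # 25 ms / 10 ms Hamming


@pytest.fixture
def sine_220():
    rate = 16_000
    t = np.arange(rate) / rate
    return Waveform(0.5 * np.sin(2 * np.pi * 220.0 * t), rate)


@pytest.fixture
def white_noise(rng):
    return Waveform(0.1 * rng.standard_normal(16_000), 16_000)
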