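import numpy as np
import pytest

from coughscope.audio import Segment
from coughscope.features import featurize_segments
from coughscope.synth import generate_segments


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone_segment():
    """3 s unit-amplitude 1 kHz sinusoid at 16 kHz."""
    rate = 16_000
    t = np.arange(3 * rate) / rate
    return Segment(np.sin(2 * np.pi * 1000.0 * t), rate)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic corpus: 60 preprocessed segments + 32x32 images."""
    segments, y, names = generate_segments(60, seed=101)
    x = featurize_segments(segments, size=32)
    return segments, x, y, names


@pytest.fixture(scope="session")
def tiny_net_cfg():
    from coughscope.nn import NetworkConfig

    return NetworkConfig(input_size=32)
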