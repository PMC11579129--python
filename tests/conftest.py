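import numpy as np
import pytest

from ndrms import make_square_layout, pair_distance_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def square22():
    """2x2 unit-pitch square layout."""
    return make_square_layout(2, 2, 1.0, 0.2)


@pytest.fixture
def hd_layout():
    """96-contact high-density grid: 8x12, 3 mm pitch, 1 mm contacts."""
    return make_square_layout(8, 12, 3.0, 1.0)


@pytest.fixture
def hd_pairs(hd_layout):
    return pair_distance_table(hd_layout)


@pytest.fixture
def sine_pair():
    """10 Hz sinusoids over 10 full cycles at 2000 Hz, as x and a
    phase-shifted copy factory."""
    t = np.arange(2000) / 2000.0

    def make(phase=0.0, freq=10.0, amplitude=1.0, offset=0.0):
        return amplitude * np.sin(2 * np.pi * freq * t + phase) + offset

    return make
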