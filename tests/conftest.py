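import numpy as np
import pytest

from dynaquad.containers import NoiseModel, SelectionWindow
from dynaquad.quadsim import QuadrupoleGeometry


@pytest.fixture
def geom() -> QuadrupoleGeometry:
    """1.1 MHz drive, 4 mm field radius."""
    return QuadrupoleGeometry()


@pytest.fixture
def window_200_10() -> SelectionWindow:
    return SelectionWindow(center=200.0, start_width=10.0, accumulation_time=10.0)


@pytest.fixture
def calibrant_noise() -> NoiseModel:
    """Stable internal-calibrant noise level (<1 % RMS)."""
    return NoiseModel(rms=0.01)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
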