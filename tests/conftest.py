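import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def unit_square():
    return [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)]


@pytest.fixture
def circle_360gon():
    """360-gon inscribed in a circle of radius 5, centered at (5, 5)."""
    th = np.linspace(0, 2 * np.pi, 361)[:-1]
    return np.column_stack([5 + 5 * np.cos(th), 5 + 5 * np.sin(th)])
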