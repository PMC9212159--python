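import numpy as np
import pytest

from kercor import KernelSpec, TimeSeriesPair
from kercor.simulate import TIME_GRID


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def noiseless_case1():
    """The phase-lagged sine pair on the fixed 18-point grid, no noise."""
    x = 2 * np.sin(TIME_GRID * np.pi / 42) - 0.5
    y = 2 * np.sin((TIME_GRID - 7) * np.pi / 42) - 0.5
    return TimeSeriesPair(x, y, times=TIME_GRID)


@pytest.fixture
def rbf_raw():
    return KernelSpec(family="rbf", gamma=0.5, standardize=False)


@pytest.fixture
def rbf_std():
    return KernelSpec(family="rbf", gamma=0.5, standardize=True)
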