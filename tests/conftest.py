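import numpy as np
import pytest

from perfkit import TimeGrid, TimeSeriesCurve
from perfkit.phantom import DEFAULT_AIF, DEFAULT_TRUTH_PARAMS, make_aif


@pytest.fixture(scope="session")
def grid():
    """100-point, 1.5 s clinical-style acquisition grid."""
    return TimeGrid.uniform(100, 1.5)


@pytest.fixture(scope="session")
def aif_blood(grid):
    return make_aif(DEFAULT_AIF["shape"], DEFAULT_AIF["params"], grid)


@pytest.fixture(scope="session")
def aif_plasma(aif_blood):
    """Haematocrit-corrected plasma AIF (Hct_a = 0.45)."""
    return aif_blood.with_values(aif_blood.values / (1.0 - 0.45))


@pytest.fixture(scope="session")
def truth_params():
    return DEFAULT_TRUTH_PARAMS


@pytest.fixture()
def zero_curve(grid):
    return TimeSeriesCurve(grid, np.zeros(grid.n))
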