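import numpy as np
import pytest

from depsort import FrequencyGrid, make_cell, make_medium


@pytest.fixture(scope="session")
def medium():
    """Low-conductivity DEP buffer: 100 uS/cm, eps_r 78."""
    return make_medium(100.0)


@pytest.fixture(scope="session")
def gbm1():
    """Control-like archetype: Cspec 20 mF/m^2."""
    return make_cell(20.0)


@pytest.fixture(scope="session")
def gbm2():
    """Resistant-like archetype: Cspec 10 mF/m^2."""
    return make_cell(10.0)


@pytest.fixture(scope="session")
def wide_band():
    return FrequencyGrid.log_spaced(1e3, 1e8, 16)


@pytest.fixture(scope="session")
def instrument_grid():
    """The 20-point, 10 kHz - 45 MHz analyzer grid."""
    return FrequencyGrid.log_spaced(1e4, 4.5e7, 20)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
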