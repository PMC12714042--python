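import numpy as np
import pytest

from dsfa_spri import (
    A_FILTER,
    AB_FILTER,
    DEFAULT_DIP,
    SceneOptics,
    WavelengthGrid,
    build_mosaic,
    default_grid,
)


@pytest.fixture(scope="session")
def grid() -> WavelengthGrid:
    return default_grid()


@pytest.fixture(scope="session")
def filter_a_spectrum(grid):
    return A_FILTER.to_spectrum(grid)


@pytest.fixture(scope="session")
def filter_ab_spectrum(grid):
    return AB_FILTER.to_spectrum(grid)


@pytest.fixture(scope="session")
def optics() -> SceneOptics:
    return SceneOptics()


@pytest.fixture(scope="session")
def dip():
    return DEFAULT_DIP


@pytest.fixture
def small_geometry():
    return build_mosaic(6, 6, 4, parity=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
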