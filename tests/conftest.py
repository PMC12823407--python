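import numpy as np
import pytest

from specdrift.afs import SelectionGrid, default_selection_grid


@pytest.fixture(scope="session")
def small_grid() -> SelectionGrid:
    """A coarse selection grid for fast unit tests."""
    return SelectionGrid.build(grid_size=12, two_N=1000)


@pytest.fixture(scope="session")
def study_grid() -> SelectionGrid:
    """The full study-design grid (50 log-spaced s_het values), cached."""
    return default_selection_grid()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
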