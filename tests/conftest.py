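import numpy as np
import pytest

from affectloop.design import Condition, label_volumes, make_default_design
from affectloop.simulate import AcquisitionGrid, make_atlas


@pytest.fixture(scope="session")
def default_design():
    return make_default_design(Condition.TENDERNESS, run_id=0)


@pytest.fixture(scope="session")
def default_labels(default_design):
    return label_volumes(default_design)


@pytest.fixture(scope="session")
def small_grid():
    return AcquisitionGrid(dims=(16, 16, 8))


@pytest.fixture(scope="session")
def small_atlas(small_grid):
    return make_atlas(small_grid, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20240522)
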