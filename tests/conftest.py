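import numpy as np
import pytest

from viadeco import (
    find_equilibria,
    make_single_cell_fixture,
    make_two_cell_fixture,
)


@pytest.fixture(scope="session")
def scenario_a():
    return make_single_cell_fixture("A")


@pytest.fixture(scope="session")
def scenario_b():
    return make_single_cell_fixture("B")


@pytest.fixture(scope="session")
def scenario_c():
    return make_single_cell_fixture("C")


@pytest.fixture(scope="session")
def scenario_c_attractors(scenario_c):
    field, region, _ = scenario_c
    return find_equilibria(field, region.bounding_box(), n_starts=16, seed=0)


@pytest.fixture(scope="session")
def two_cell():
    return make_two_cell_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
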