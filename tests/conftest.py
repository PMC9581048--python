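import pytest

from cyton2.distributions import make_distribution
from cyton2.mean_model import CytonParameters


@pytest.fixture
def point_mass_params():
    """Hand-checkable family: divisions at 40/50/60 h, destiny 65 h,
    death 100 h -> live counts 1 -> 2 -> 4 -> 8 -> 0."""
    return CytonParameters(
        dist_div0=make_distribution("point_mass", t0=40.0),
        subsequent=10.0,
        dist_dd=make_distribution("point_mass", t0=65.0),
        dist_die=make_distribution("point_mass", t0=100.0),
        n0=1.0)


@pytest.fixture
def b_like_params():
    from cyton2.synthetic import b_cell_like_parameters
    return b_cell_like_parameters(n0=1.0)


@pytest.fixture
def t_like_params():
    from cyton2.synthetic import t_cell_like_parameters
    return t_cell_like_parameters(n0=1.0)


@pytest.fixture
def toy_tree():
    """Two-generation clone: founder divides at 40, gen-1 cells divide at
    50 and 52, the four gen-2 cells die at 100, 102, 98, 100."""
    from cyton2.trees import Cell, FamilyTree
    cells = [
        Cell((), "divided", 40.0),
        Cell((1,), "divided", 50.0),
        Cell((2,), "divided", 52.0),
        Cell((1, 1), "died", 100.0),
        Cell((1, 2), "died", 102.0),
        Cell((2, 1), "died", 98.0),
        Cell((2, 2), "died", 100.0),
    ]
    return FamilyTree.from_cells("toy", cells)
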