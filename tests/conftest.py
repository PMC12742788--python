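import pytest

from gaitscape.limit_cycle import (GaitSpec, continuation_sweep,
                                   solve_limit_cycle_continued)
from gaitscape.linearization import linearize_gait
from gaitscape.control import build_controller
from gaitscape.policy import build_gain_grid
from gaitscape.workbench import make_fixture_grid


@pytest.fixture(scope="session")
def centre_gait():
    """Converged periodic gait at the centre of the gait space,
    reached by continuation from the reference corner."""
    g = solve_limit_cycle_continued(GaitSpec(0.6, 0.6))
    assert g.converged
    return g


@pytest.fixture(scope="session")
def centre_maps(centre_gait):
    return linearize_gait(centre_gait, mode="double")


@pytest.fixture(scope="session")
def centre_controller(centre_gait, centre_maps):
    return build_controller(centre_gait, centre_maps)


@pytest.fixture(scope="session")
def fixture_grid():
    """Fully solved 7x7 sub-grid around (0.6, 0.6) at 0.01 increment."""
    return make_fixture_grid((0.6, 0.6), half_width=0.03, increment=0.01)


@pytest.fixture(scope="session")
def coarse_grid():
    """Every-5th-cell sub-sample of the full gait space (21x21 at 0.05)."""
    return continuation_sweep((0.1, 1.1), (0.1, 1.1), 0.05)


@pytest.fixture(scope="session")
def policy_patch(centre_gait):
    """Gain grid over the centre region, wide enough for +/-15% targets."""
    grid = continuation_sweep((0.48, 0.72), (0.48, 0.72), 0.01,
                              seed_gait=centre_gait)
    assert grid.n_converged == 625
    return build_gain_grid(grid)
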