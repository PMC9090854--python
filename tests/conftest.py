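import numpy as np
import pytest

from dermaplex import (
    GeometryParams,
    TransportParams,
    build_unit_cell,
    classify_nodes,
    steady_state,
)

# Coarse study grid: 20 um spacing resolves a 20 um lumen and gives the
# 12 x 12 x 40 unit cell used throughout the fast tests.
COARSE_H = 20.0


@pytest.fixture(scope="session")
def coarse_geometry():
    return build_unit_cell(GeometryParams(lumen_diameter=20.0))


@pytest.fixture(scope="session")
def coarse_grid(coarse_geometry):
    return classify_nodes(coarse_geometry, COARSE_H)


@pytest.fixture(scope="session")
def standard_params():
    return TransportParams()


@pytest.fixture(scope="session")
def coarse_steady(coarse_geometry, standard_params, coarse_grid):
    return steady_state(coarse_geometry, standard_params, COARSE_H, grid=coarse_grid)


@pytest.fixture(scope="session")
def fine_geometry():
    return build_unit_cell(GeometryParams())


@pytest.fixture(scope="session")
def fine_steady(fine_geometry, standard_params):
    # the standard 10 um lumen at 10 um spacing (24 x 24 x 80 nodes)
    return steady_state(fine_geometry, standard_params, 10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
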