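import numpy as np
import pytest

import dcbsim as d
from dcbsim.parameters import DC, FF, FI, HT, NC


@pytest.fixture(scope="session")
def params():
    return d.ModelParameters()


@pytest.fixture(scope="session")
def annulus_grid():
    """Coarse single-label annulus: lumen radius 1.5 mm, wall 0.5 mm."""
    return d.make_circular_phantom(1.5, 0.5, 0.04)


@pytest.fixture(scope="session")
def ref_phantom():
    """Scattered phantom with the reference plaque composition."""
    return d.make_heterogeneous_phantom(d.scenarios.ref_phantom_spec())


@pytest.fixture(scope="session")
def thick_annulus_flow(params):
    """Steady flow on an annulus thick enough to probe r = 2 r_i."""
    grid = d.make_circular_phantom(1.0, 1.2, 0.05)
    field = d.solve_interstitial_flow(grid, params)
    return grid, field


@pytest.fixture(scope="session")
def validation_run(params):
    """Circular-vessel validation: 30 s inflation then 21 min washing."""
    grid = d.scenarios.validation_geometry(pixel_size=0.02)
    scen = d.scenarios.validation_scenario(t_post_minutes=21.0)
    return d.run_simulation(grid, params, scen)


def radial_coordinates(grid):
    ny, nx = grid.shape
    h = grid.pixel_size
    jj, ii = np.mgrid[0:ny, 0:nx]
    cx = nx * h / 2.0
    cy = ny * h / 2.0
    return np.hypot((ii + 0.5) * h - cx, (jj + 0.5) * h - cy)
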