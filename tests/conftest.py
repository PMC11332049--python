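import numpy as np
import pandas as pd
import pytest

from phenoshift import synthetic as synth
from phenoshift.grids import GridSpec
from phenoshift.projection import LambertAzimuthalEqualArea


@pytest.fixture(scope="session")
def projection():
    return LambertAzimuthalEqualArea()


@pytest.fixture(scope="session")
def small_landscape():
    """A 6 x 6 cell synthetic landscape (grid + covariates)."""
    return synth.make_landscape(n_cols=6, n_rows=6, seed=42)


@pytest.fixture(scope="session")
def flat_grid(projection):
    """A 4 x 4 grid with hand-set covariates for exact-arithmetic tests."""
    x0, y0 = projection.forward(8.0, 48.0)
    grid = GridSpec(origin_x=float(x0), origin_y=float(y0), cell_size=50_000.0,
                    n_cols=4, n_rows=4, projection=projection)
    lon, lat = grid.centroids_lonlat()
    rng = np.random.default_rng(7)
    cov = pd.DataFrame({
        "cell_id": np.arange(grid.n_cells),
        "elev": rng.uniform(0, 2000, grid.n_cells),
        "lat": lat,
        "lon": lon,
    })
    return grid, cov
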