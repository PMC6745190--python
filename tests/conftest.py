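import numpy as np
import pytest

from ecoserv import (
    CategoricalRaster,
    central_asia_area_table,
    central_asia_coefficients,
)
from ecoserv.classes import CLASSES, NODATA


@pytest.fixture(scope="session")
def areas():
    return central_asia_area_table()


@pytest.fixture(scope="session")
def vc():
    return central_asia_coefficients()


def make_raster(grid, cell_area_ha=1.0, year=None):
    """Build a CategoricalRaster from a list-of-lists of class indices."""
    return CategoricalRaster(np.asarray(grid, dtype=np.int16), cell_area_ha=cell_area_ha, year=year)


@pytest.fixture
def checkerboard():
    """8x8 two-class (cropland/grassland) checkerboard, 1 ha cells."""
    g = np.indices((8, 8)).sum(axis=0) % 2
    vals = np.where(g == 0, CLASSES.index("cropland"), CLASSES.index("grassland"))
    return make_raster(vals)


@pytest.fixture
def masked_pair():
    """Two 4x4 rasters with different nodata holes, for harmonization tests."""
    a = np.full((4, 4), CLASSES.index("grassland"), dtype=np.int16)
    b = np.full((4, 4), CLASSES.index("grassland"), dtype=np.int16)
    a[0, 0] = NODATA
    b[3, 3] = NODATA
    b[1, 1] = CLASSES.index("cropland")
    return make_raster(a), make_raster(b)
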