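import numpy as np
import pytest

from demicwave.chronology import CalibratedDensity
from demicwave.raster import GridRaster


def flat_dem(nr=32, nc=32, cell=0.1, lat0=50.0, elev=100.0, mask=None):
    """A constant-elevation DEM centred near (0 E, lat0 N)."""
    vals = np.full((nr, nc), float(elev))
    if mask is not None:
        vals = vals.copy()
        vals[mask] = np.nan
    return GridRaster(
        vals, (0.0, lat0, cell, cell),
        nodata_mask=mask if mask is not None else None, units="m",
    )


def gaussian_density(mean, sd, step=5.0, halfwidth=8.0):
    """A discretised Gaussian calendar-age density."""
    lo = mean - halfwidth * sd
    hi = mean + halfwidth * sd
    # align the grid to multiples of step so different densities share atoms
    grid = np.arange(np.floor(lo / step) * step, hi + step, step)
    w = np.exp(-((grid - mean) ** 2) / (2.0 * sd**2))
    return CalibratedDensity(grid, w / w.sum())


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
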