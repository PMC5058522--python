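import numpy as np
import pandas as pd
import pytest

from udshift.grids import GridSpec, Raster


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    """10 x 10 grid of 250-m cells."""
    return GridSpec(0.0, 0.0, 250.0, 10, 10)


def make_track(xy, times, animal_id="a1", dop=2.0):
    """Build a fix table from coordinate and timestamp sequences."""
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame({
        "animal_id": animal_id,
        "t": pd.to_datetime(times, utc=True),
        "x": xy[:, 0], "y": xy[:, 1],
        "dop": dop if np.isscalar(dop) else np.asarray(dop, dtype=float),
    })


def random_mass_raster(grid, rng):
    v = rng.random(grid.shape)
    return Raster(grid, v / v.sum(), "mass")
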