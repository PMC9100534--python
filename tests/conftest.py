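import numpy as np
import pandas as pd
import pytest

from cnm.grids import EnvGrid, GridStack
from cnm import synthetic_data as sd


@pytest.fixture(scope="session")
def small_world():
    """A 40x40 synthetic study system shared by read-only tests."""
    return sd.make_world(nrows=40, ncols=40, n_presences=150, n_zones=6, seed=11)


@pytest.fixture()
def flat_grid():
    """A 4x5 all-valid grid of zeros at 2.5 arc-minutes."""
    return EnvGrid(np.zeros((4, 5)), -110.0, 30.0, 2.5)


def make_grid(values, origin_lon=-110.0, origin_lat=30.0, cell_size=2.5,
              mask=None):
    return EnvGrid(np.asarray(values, dtype=float), origin_lon, origin_lat,
                   cell_size, mask)


def make_occ(lons, lats, retained=None):
    n = len(lons)
    return pd.DataFrame(
        {
            "record_id": [f"r{i:03d}" for i in range(n)],
            "lon": lons,
            "lat": lats,
            "retained": [True] * n if retained is None else retained,
            "drop_reason": "none",
        }
    )
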