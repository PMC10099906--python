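import numpy as np
import pandas as pd
import pytest
import xarray as xr

from habshift.env_match import EnvStack
from habshift.synthetic_world import Colony, WorldConfig, make_world

TEST_COLONIES = (Colony("col_A", 10.5, -52.5, 30000),
                 Colony("col_B", 30.5, -53.5, 10000))


def make_stack(values: dict, lats=None, lons=None, times=None) -> EnvStack:
    """Small EnvStack from per-layer 2-D (or (time, lat, lon)) arrays."""
    first = next(iter(values.values()))
    first = np.asarray(first, dtype=float)
    if times is not None:
        nt, ny, nx = first.shape
    else:
        ny, nx = first.shape
    lats = np.arange(-60.0 + 0.5, -60.0 + ny) if lats is None else np.asarray(lats, float)
    lons = np.arange(0.5, nx) if lons is None else np.asarray(lons, float)
    coords = {"lat": lats, "lon": lons}
    dims = ("lat", "lon")
    if times is not None:
        coords = {"time": pd.to_datetime(times), **coords}
        dims = ("time", "lat", "lon")
    return EnvStack(xr.Dataset(
        {k: (dims, np.asarray(v, dtype=float)) for k, v in values.items()},
        coords=coords))


def all_sea_masks(ny=30, nx=40, lat0=-65.0, lon0=0.0):
    lats = np.arange(lat0 + 0.5, lat0 + ny)
    lons = np.arange(lon0 + 0.5, lon0 + nx)
    false = np.zeros((ny, nx), dtype=bool)
    da = xr.DataArray(false, coords={"lat": lats, "lon": lons},
                      dims=("lat", "lon"))
    return da.copy(), da.copy()


@pytest.fixture(scope="session")
def small_world():
    """Compact world shared by unit tests (cheap to simulate from)."""
    cfg = WorldConfig(lon_min=0, lon_max=40, lat_min=-65, lat_max=-40,
                      colonies=TEST_COLONIES,
                      n_individuals=6, trip_days=15.0, seed=7)
    return make_world(cfg)


@pytest.fixture(scope="session")
def noise_free_world():
    """Deterministic zonal world: no spatial/daily noise, no land."""
    cfg = WorldConfig(lon_min=0, lon_max=40, lat_min=-65, lat_max=-35,
                      colonies=TEST_COLONIES,
                      noise_sst=0.0, noise_ssh=0.0, daily_noise_sst=0.0,
                      daily_noise_ssh=0.0, land_fraction=0.0,
                      n_representations=2, rep_noise_sd=0.0, seed=11)
    return make_world(cfg)
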