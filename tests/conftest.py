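import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")

from bambooclim import synthetic_data as sd
from bambooclim.cli_io import station_summaries


def grid(values, lat=None, lon=None, **attrs) -> xr.DataArray:
    """Small helper to build a lat/lon DataArray from a 2-D array."""
    values = np.asarray(values, dtype=float)
    ny, nx = values.shape
    lat = np.linspace(35.0, 45.0, ny) if lat is None else np.asarray(lat)
    lon = np.linspace(136.0, 145.0, nx) if lon is None else np.asarray(lon)
    return xr.DataArray(
        values, coords={"lat": lat, "lon": lon}, dims=("lat", "lon"), attrs=attrs
    )


@pytest.fixture(scope="session")
def world():
    """A mid-size synthetic station world with known coefficients."""
    spec = sd.SyntheticWorldSpec(n_stations=400, seed=42)
    table, truth = sd.make_stations(spec)
    return spec, table, truth


@pytest.fixture(scope="session")
def summaries(world):
    _, table, _ = world
    return station_summaries(table)
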