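"""Synthetic station networks, climate grids, and warming series with known truth.

Every pipeline stage can be exercised without external data: stations are
laid out along a latitude-altitude temperature gradient with a sinusoidal
seasonal cycle, presence is drawn from a known logistic model of mean annual
temperature and sun radiation, paired present/future grids carry a known
warming pattern, and the global anomaly series is a monotone ramp anchored
at zero in the 1990 reference year.

Defaults emulate a temperate station network of 145 sites between 35.3 and
41.5°N with roughly four presences per absence and a logistic occupancy
transition spanning 7-11°C mean annual temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy.special import expit

from .scenario_scaling import GlobalAnomalySeries

MONTHS = np.arange(1, 13)
SEASONAL_AMPLITUDE_C = 11.0  # °C, peak-to-mean of the monthly cycle
REFERENCE_YEAR = 1990


class SyntheticSpecError(ValueError):
    """Raised for degenerate synthetic-world specifications."""


@dataclass(frozen=True)
class SyntheticWorldSpec:
    """Ground-truth description of a synthetic station world.

    ``true_coefficients`` are (intercept, per-°C temperature slope, per
    MJ m⁻² day⁻¹ radiation slope) on the logit scale. The default intercept
    centres the occupancy transition near 9°C at mid-range radiation.
    """

    n_stations: int = 145
    lat_range: tuple[float, float] = (35.3, 41.5)
    lon_range: tuple[float, float] = (137.6, 142.0)
    alt_range: tuple[float, float] = (0.0, 1200.0)  # m
    lapse_rate: float = -6.5  # °C per km of altitude
    lat_gradient: float = -1.0  # °C per degree latitude northward
    sea_level_temp: float = 16.0  # °C at the southern edge, sea level
    true_coefficients: tuple[float, float, float] = (-18.4, 1.5, 0.35)
    radiation_range: tuple[float, float] = (12.0, 16.0)
    noise_sd: float = 0.6  # °C station-to-station microclimate scatter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stations < 2:
            raise SyntheticSpecError("need at least 2 stations")
        for name in ("lat_range", "alt_range", "radiation_range"):
            lo, hi = getattr(self, name)
            if not hi > lo:
                raise SyntheticSpecError(f"{name} has zero or negative spread")
        if self.noise_sd < 0:
            raise SyntheticSpecError("noise_sd must be non-negative")


def _seasonal_cycle(mean_temp: np.ndarray) -> np.ndarray:
    """Monthly means as a sinusoid around the annual mean, peaking in August.

    The twelve phase points sum to zero exactly, so the monthly mean equals
    the annual mean to arithmetic precision.
    """
    phase = np.cos(2.0 * np.pi * (MONTHS - 8) / 12.0)
    return mean_temp[:, None] + SEASONAL_AMPLITUDE_C * phase[None, :]


def make_stations(
    spec: SyntheticWorldSpec,
) -> tuple[pd.DataFrame, dict]:
    """Generate a station table plus the generating truth.

    Returns ``(table, truth)``: the table uses the station CSV dialect
    (columns ``t_01..t_12``, ``p_01..p_12``, ``tmin_year``, ``tmax_year``,
    ``radiation``, land-use ratios, ``presence``); ``truth`` holds the
    logit-scale coefficients and the per-station occupancy probabilities.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_stations

    lat = rng.uniform(*spec.lat_range, size=n)
    lon = rng.uniform(*spec.lon_range, size=n)
    # station networks sit mostly at low altitude; Beta(1,4) skews accordingly
    alt = spec.alt_range[0] + (spec.alt_range[1] - spec.alt_range[0]) * rng.beta(
        1.0, 4.0, size=n
    )
    mean_temp = (
        spec.sea_level_temp
        + spec.lat_gradient * (lat - spec.lat_range[0])
        + spec.lapse_rate * alt / 1000.0
        + rng.normal(0.0, spec.noise_sd, size=n)
    )
    radiation = rng.uniform(*spec.radiation_range, size=n)

    monthly_t = _seasonal_cycle(mean_temp)
    # wetter summers; gamma noise keeps totals positive
    precip_base = rng.uniform(60.0, 120.0, size=n)
    summer_boost = 1.0 + 0.6 * np.sin(np.pi * (MONTHS - 0.5) / 12.0)
    monthly_p = precip_base[:, None] * summer_boost[None, :] * rng.gamma(
        8.0, 1.0 / 8.0, size=(n, 12)
    )

    tmin_year = monthly_t.min(axis=1) - rng.uniform(6.0, 10.0, size=n)
    tmax_year = monthly_t.max(axis=1) + rng.uniform(8.0, 12.0, size=n)

    landuse = rng.dirichlet((4.0, 2.0, 1.0, 1.5), size=n)  # forest, farm, build, other
    b0, b_t, b_r = spec.true_coefficients
    prob = expit(b0 + b_t * mean_temp + b_r * radiation)
    presence = rng.binomial(1, prob)

    table = pd.DataFrame(
        {
            "station_id": [f"S{i:05d}" for i in range(n)],
            "lat": lat,
            "lon": lon,
            "altitude": alt,
        }
    )
    for m in range(12):
        table[f"t_{m + 1:02d}"] = monthly_t[:, m]
    for m in range(12):
        table[f"p_{m + 1:02d}"] = monthly_p[:, m]
    table["tmin_year"] = tmin_year
    table["tmax_year"] = tmax_year
    table["radiation"] = radiation
    table["forest_ratio"] = landuse[:, 0]
    table["farmland_ratio"] = landuse[:, 1]
    table["building_ratio"] = landuse[:, 2]
    table["presence"] = presence.astype(int)

    truth = {
        "coefficients": {
            "intercept": b0,
            "mean_annual_temp": b_t,
            "radiation": b_r,
        },
        "probability": prob.copy(),
        "mean_annual_temp": mean_temp.copy(),
    }
    return table, truth


@dataclass(frozen=True)
class WarmingFieldSpec:
    """Spatial shape of the warming between the present and future grids.

    ``lat_slope`` tilts warming with latitude (fractional change per degree
    about the area-weighted mean latitude), so the area-weighted mean
    warming over land stays ``global_dT * regional_amplification`` exactly.
    """

    lat_slope: float = 0.0
    regional_amplification: float = 1.0
    radiation_change_frac: float = -0.02


def _land_mask(lat2d: np.ndarray, lon2d: np.ndarray) -> np.ndarray:
    """Deterministic wavy 'coastline': sea along the western margin."""
    lon_min, lon_max = lon2d.min(), lon2d.max()
    lat_min, lat_max = lat2d.min(), lat2d.max()
    width = lon_max - lon_min
    span = max(lat_max - lat_min, 1e-9)
    coast = lon_min + width * (0.10 + 0.08 * np.sin(np.pi * (lat2d - lat_min) / span))
    return lon2d >= coast


def make_grid_world(
    extent: tuple[float, float, float, float] = (34.0, 46.0, 135.0, 146.0),
    resolution: float = 0.25,
    warming_field_spec: WarmingFieldSpec = WarmingFieldSpec(),
    global_dT: float = 3.5,
    seed: int = 0,
) -> tuple[xr.Dataset, xr.Dataset]:
    """Paired present/future grids (mean annual temperature, sun radiation).

    ``extent`` is (lat_min, lat_max, lon_min, lon_max); cell centres start
    half a cell inside. Sea cells are NaN in both periods. Returns
    ``(present, future)`` sharing coordinates and mask; the future dataset
    records ``global_dT`` in its attrs.
    """
    if global_dT <= 0:
        raise SyntheticSpecError("global_dT must be positive")
    lat_min, lat_max, lon_min, lon_max = extent
    if not (lat_max > lat_min and lon_max > lon_min):
        raise SyntheticSpecError("degenerate grid extent")
    rng = np.random.default_rng(seed)

    lat = np.arange(lat_min + resolution / 2, lat_max, resolution)
    lon = np.arange(lon_min + resolution / 2, lon_max, resolution)
    lon2d, lat2d = np.meshgrid(lon, lat)
    land = _land_mask(lat2d, lon2d)

    # smooth pseudo-terrain from a few random Fourier modes
    terrain = np.zeros_like(lat2d)
    for _ in range(6):
        kx, ky = rng.uniform(0.2, 1.2, size=2)
        ph = rng.uniform(0, 2 * np.pi, size=2)
        terrain += rng.uniform(0, 250.0) * (
            np.sin(kx * lon2d + ph[0]) * np.sin(ky * lat2d + ph[1]) + 1.0
        )
    temp = 16.0 - 1.0 * (lat2d - 35.3) - 6.5 * terrain / 1000.0
    radiation = 14.0 + 1.0 * np.sin(0.8 * lon2d) * np.cos(0.6 * lat2d)

    w = warming_field_spec
    coslat = np.cos(np.radians(lat2d))
    wsum = (coslat * land).sum()
    lat_c = (lat2d * coslat * land).sum() / wsum
    warming = (
        global_dT
        * w.regional_amplification
        * (1.0 + w.lat_slope * (lat2d - lat_c))
    )

    def dataset(t: np.ndarray, r: np.ndarray, period: str) -> xr.Dataset:
        tt = np.where(land, t, np.nan)
        rr = np.where(land, r, np.nan)
        ds = xr.Dataset(
            {
                "temperature": (("lat", "lon"), tt, {"units": "degC"}),
                "radiation": (("lat", "lon"), rr, {"units": "MJ m-2 day-1"}),
            },
            coords={"lat": lat, "lon": lon},
            attrs={"period": period},
        )
        return ds

    present = dataset(temp, radiation, "present")
    future = dataset(
        temp + warming, radiation * (1.0 + w.radiation_change_frac), "future"
    )
    future.attrs["global_dT"] = float(global_dT)
    return present, future


def make_anomaly_series(
    start_year: int = 1990,
    end_year: int = 2090,
    shape: str = "linear",
    rate: float = 0.02,
    preindustrial_offset: float = 0.5,
) -> GlobalAnomalySeries:
    """Monotone global-mean warming anomaly, zero at the 1990 reference.

    ``rate`` is °C/yr: the constant slope for ``shape='linear'`` or the peak
    slope (at mid-century) for ``shape='logistic'``.
    """
    if end_year <= start_year:
        raise SyntheticSpecError("end_year must exceed start_year")
    if rate < 0:
        raise SyntheticSpecError("rate must be non-negative")
    years = np.arange(start_year, end_year + 1)
    if shape == "linear":
        anomaly = rate * (years - REFERENCE_YEAR)
    elif shape == "logistic":
        ceiling, midpoint = 5.0, 2050.0
        k = 4.0 * rate / ceiling
        anomaly = ceiling * (
            expit(k * (years - midpoint)) - expit(k * (REFERENCE_YEAR - midpoint))
        )
    else:
        raise SyntheticSpecError(f"unknown anomaly shape {shape!r}")
    return GlobalAnomalySeries(
        years=years,
        anomaly=anomaly.astype(float),
        window=20,
        preindustrial_offset=preindustrial_offset,
    )
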