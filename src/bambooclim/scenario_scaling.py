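"""Pattern scaling of regional climate change to arbitrary warming levels.

A single present/future regional simulation pair fixes the *spatial shape*
of climate change; dividing the 20-year mean difference by the simulation's
global-mean warming gives a scaling pattern (change per 1°C of global
warming). A scenario at X°C above preindustrial is then

    scenario = baseline + (X - offset) * pattern

where ``offset`` (default 0.5°C) is the warming already realised between the
preindustrial period and the present-day baseline. The year at which a
warming level is reached is read off a 20-year running-mean global anomaly
series referenced to 1990.

Grids are xarray objects with ``lat``/``lon`` cell-centre coordinates; sea
or off-domain cells are NaN and stay NaN through every operation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

DEFAULT_PREINDUSTRIAL_OFFSET = 0.5  # °C above preindustrial at the 1990 baseline


class GridGeometryError(ValueError):
    """Raised when two grids do not share shape and coordinates."""


class ScalingDomainError(ValueError):
    """Raised for out-of-domain scalar arguments (e.g. non-positive dT)."""


def _check_geometry(a: xr.DataArray, b: xr.DataArray) -> None:
    if a.shape != b.shape:
        raise GridGeometryError(f"grid shapes differ: {a.shape} vs {b.shape}")
    for dim in ("lat", "lon"):
        if dim not in a.coords or dim not in b.coords:
            raise GridGeometryError(f"grids must carry a {dim!r} coordinate")
        if not np.allclose(a[dim].values, b[dim].values):
            raise GridGeometryError(f"{dim} coordinates differ")
    # masks must agree so masked cells never acquire values
    if not np.array_equal(np.isnan(a.values), np.isnan(b.values)):
        raise GridGeometryError("NaN masks differ between grids")


@dataclass(frozen=True)
class GlobalAnomalySeries:
    """20-year running-mean global temperature anomaly relative to 1990."""

    years: np.ndarray
    anomaly: np.ndarray  # °C relative to the 1990 (1980-2000) reference
    window: int = 20
    preindustrial_offset: float = DEFAULT_PREINDUSTRIAL_OFFSET

    def __post_init__(self) -> None:
        if len(self.years) != len(self.anomaly):
            raise ScalingDomainError("years and anomaly lengths differ")


def compute_scaling_pattern(
    present: xr.DataArray, future: xr.DataArray, global_dT: float
) -> xr.DataArray:
    """Per-cell change per 1°C of global-mean warming.

    ``global_dT`` is the global-mean temperature difference between the two
    simulation periods (e.g. 3.49-3.57°C across a four-member SST ensemble
    under a high-emissions pathway).
    """
    if global_dT <= 0:
        raise ScalingDomainError("global_dT must be positive")
    _check_geometry(present, future)
    pattern = (future - present) / global_dT
    pattern.attrs["global_dT"] = float(global_dT)
    pattern.attrs["units"] = f"{present.attrs.get('units', '')} per degC global"
    return pattern


def build_scenario(
    baseline: xr.DataArray,
    pattern: xr.DataArray,
    warming_level: float,
    preindustrial_offset: float = DEFAULT_PREINDUSTRIAL_OFFSET,
) -> xr.DataArray:
    """Climate field at ``warming_level`` °C above preindustrial.

    The pattern is inflated by (warming_level - offset) because the baseline
    period already sits ``offset`` °C above preindustrial; at
    ``warming_level == offset`` the scenario is the baseline, bit for bit.
    """
    _check_geometry(baseline, pattern)
    if warming_level < preindustrial_offset:
        raise ScalingDomainError(
            f"warming level {warming_level} below the preindustrial offset "
            f"{preindustrial_offset} of the baseline"
        )
    if warming_level == preindustrial_offset:
        scenario = baseline.copy(deep=True)
    else:
        scenario = baseline + (warming_level - preindustrial_offset) * pattern
    scenario.attrs.update(baseline.attrs)
    scenario.attrs["warming_level"] = float(warming_level)
    return scenario


def running_mean(
    years: np.ndarray, values: np.ndarray, window: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Centered running mean; each output labeled by its window midpoint year.

    Years y..y+19 are labeled y+10, so an annual series 1980..2099 yields
    labels 1990..2090. Output length is n - window + 1.
    """
    years = np.asarray(years)
    values = np.asarray(values, dtype=float)
    n = len(values)
    if len(years) != n:
        raise ScalingDomainError("years and values lengths differ")
    if n < window:
        raise ScalingDomainError(f"series of length {n} shorter than window {window}")
    kernel = np.ones(window) / window
    means = np.convolve(values, kernel, mode="valid")
    labels = years[: n - window + 1] + window // 2
    return labels, means


def exceedance_year(series: GlobalAnomalySeries, warming_level: float) -> int | None:
    """First year whose anomaly reaches ``warming_level`` above preindustrial.

    The comparison is inclusive (anomaly >= level - offset). Returns None if
    the level is never reached within the series.
    """
    if warming_level < series.preindustrial_offset:
        raise ScalingDomainError(
            "warming level below the preindustrial offset of the series"
        )
    target = warming_level - series.preindustrial_offset
    hits = np.nonzero(series.anomaly >= target - 1e-12)[0]
    if hits.size == 0:
        return None
    return int(series.years[hits[0]])


RADIATION_GUARD = 1e-6


def bias_correct(
    simulated: xr.DataArray,
    observed_reference: xr.DataArray,
    mode: str = "additive",
    target: xr.DataArray | None = None,
) -> xr.DataArray:
    """Per-cell mean-matching bias correction against an observed reference.

    The correction is estimated from the simulated present-period field and
    the observed reference, then applied to ``target`` (default: the
    simulated field itself, whose corrected mean then equals the reference
    exactly; pass the future field to correct it with the same offsets).
    ``mode='additive'`` (temperature) subtracts the per-cell simulated-minus-
    observed offset; ``mode='multiplicative'`` (radiation) rescales by the
    per-cell observed/simulated ratio, leaving cells with a near-zero
    simulated value uncorrected. Deliberately simple — the correction is
    isolated behind this one interface so a quantile-mapping or other recipe
    can replace it without touching the scaling steps.
    """
    _check_geometry(simulated, observed_reference)
    if target is None:
        target = simulated
    else:
        _check_geometry(simulated, target)
    if mode == "additive":
        corrected = target + (observed_reference - simulated)
    elif mode == "multiplicative":
        sim = simulated.values
        obs = observed_reference.values
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where(np.abs(sim) > RADIATION_GUARD, obs / sim, 1.0)
        corrected = target * xr.DataArray(
            factor, coords=target.coords, dims=target.dims
        )
    else:
        raise ScalingDomainError(f"unknown bias-correction mode {mode!r}")
    corrected.attrs.update(target.attrs)
    corrected.attrs["bias_corrected"] = mode
    return corrected
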