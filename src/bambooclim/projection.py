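"""Habitat projection: probability grids, thresholded habitat maps,
area fractions, northern-limit shifts, and MESS extrapolation diagnostics.

A fitted niche model is applied cellwise to climate grids, thresholded at
the validation cutoff (inclusive: habitat iff probability >= τ), and
summarised over a focal region (default: land north of 35°N and east of
136°E). Because scenario grids can leave the climate envelope the model was
calibrated on, the multivariate environmental similarity surface (MESS)
flags cells whose conditions fall outside the reference stations' range
(negative similarity = novel conditions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.special import expit

from .niche_model import FittedNicheModel
from .scenario_scaling import GridGeometryError, _check_geometry

KM_PER_DEGREE_LAT = 111.2  # mean meridian arc
DEFAULT_REGION = {"lat_min": 35.0, "lon_min": 136.0}  # inclusive bounds
DEFAULT_THRESHOLD = 0.606


class ProjectionError(ValueError):
    """Raised for inconsistent projection inputs."""


def predict_grid(
    model: FittedNicheModel, grids: dict[str, xr.DataArray]
) -> xr.DataArray:
    """Cellwise occupancy probability logit⁻¹(β·x); NaN cells propagate."""
    missing = [n for n in model.predictor_names if n not in grids]
    if missing:
        raise ProjectionError(f"missing predictor grids: {missing}")
    arrays = list(grids.values())
    for other in arrays[1:]:
        _check_geometry(arrays[0], other)
    template = arrays[0] if arrays else None
    if template is None:
        raise ProjectionError("at least one predictor grid required")
    eta = xr.full_like(template, model.coefficients["intercept"])
    for name in model.predictor_names:
        eta = eta + model.coefficients[name] * grids[name]
    prob = xr.apply_ufunc(expit, eta)
    prob.attrs["long_name"] = "occupancy probability"
    return prob


def threshold_map(probability: xr.DataArray, tau: float) -> xr.DataArray:
    """Binary habitat map: habitat iff probability >= tau; NaN stays NaN."""
    vals = probability.values
    habitat = np.where(np.isnan(vals), np.nan, (vals >= tau).astype(float))
    out = xr.DataArray(habitat, coords=probability.coords, dims=probability.dims)
    out.attrs["threshold"] = float(tau)
    return out


def region_mask(
    grid: xr.DataArray,
    lat_min: float = DEFAULT_REGION["lat_min"],
    lon_min: float = DEFAULT_REGION["lon_min"],
) -> xr.DataArray:
    """Land cells within the focal region (inclusive >= bounds)."""
    lat2d, lon2d = xr.broadcast(grid["lat"], grid["lon"])
    inside = (lat2d >= lat_min) & (lon2d >= lon_min)
    land = ~np.isnan(grid.values)
    return xr.DataArray(
        inside.values & land, coords=grid.coords, dims=grid.dims
    )


def habitat_fraction(
    habitat: xr.DataArray, mask: xr.DataArray, cos_lat_weight: bool = False
) -> float:
    """Habitat cells / masked land cells.

    Plain cell counting by default (near-equal-area at mid-latitude regional
    scale); cos(latitude) weighting behind the flag corrects the residual
    poleward shrinkage of cells on a regular lat/lon grid.
    """
    m = np.asarray(mask.values, dtype=bool)
    if not m.any():
        raise ProjectionError("empty region mask")
    h = np.nan_to_num(habitat.values, nan=0.0)
    if cos_lat_weight:
        lat2d, _ = xr.broadcast(habitat["lat"], habitat["lon"])
        w = np.cos(np.radians(lat2d.values))
        return float((h * w)[m].sum() / w[m].sum())
    return float(h[m].sum() / m.sum())


def northern_limit(habitat: xr.DataArray, mask: xr.DataArray | None = None) -> float | None:
    """Maximum cell-centre latitude with habitat (None if no habitat)."""
    h = np.nan_to_num(habitat.values, nan=0.0) > 0
    if mask is not None:
        h = h & np.asarray(mask.values, dtype=bool)
    if not h.any():
        return None
    lat2d, _ = xr.broadcast(habitat["lat"], habitat["lon"])
    return float(lat2d.values[h].max())


def northward_shift(base_limit: float, scenario_limit: float) -> float:
    """Northward displacement of the habitat limit in km (meridian arc)."""
    return (scenario_limit - base_limit) * KM_PER_DEGREE_LAT


def mess_similarity(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """MESS similarity of values against a reference sample, one variable.

    With f the percentage of reference points strictly below v and
    (min, max) the reference extremes:
      f = 0    -> 100 * (v - min) / (max - min)   (negative below the range)
      0<f<=50  -> 2f
      50<f<100 -> 2(100 - f)
      f = 100  -> 100 * (max - v) / (max - min)   (negative above the range)
    A degenerate reference (max == min) scores 100 at the single value and
    0 elsewhere, with a warning.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.size < 2:
        raise ProjectionError("need at least 2 reference points per variable")
    v = np.asarray(values, dtype=float)
    rmin, rmax = ref.min(), ref.max()
    n = ref.size
    f = 100.0 * np.searchsorted(np.sort(ref), v, side="left") / n
    span = rmax - rmin
    if span == 0:
        warnings.warn("degenerate reference (all values equal) in MESS")
        return np.where(v == rmin, 100.0, 0.0)
    out = np.empty_like(v, dtype=float)
    below = f == 0
    above = f == 100
    lower = (f > 0) & (f <= 50)
    upper = (f > 50) & (f < 100)
    out[below] = 100.0 * (v[below] - rmin) / span
    out[lower] = 2.0 * f[lower]
    out[upper] = 2.0 * (100.0 - f[upper])
    out[above] = 100.0 * (rmax - v[above]) / span
    out[np.isnan(v)] = np.nan
    return out


@dataclass(frozen=True)
class MESSSurface:
    similarity: xr.DataArray  # per-cell minimum similarity across variables
    most_dissimilar: xr.DataArray  # integer index into variable_names (NaN masked)
    variable_names: tuple[str, ...]

    def negative_fraction(self, mask: xr.DataArray | None = None) -> float:
        """Fraction of (masked) cells in novel conditions (similarity < 0)."""
        s = self.similarity.values
        valid = ~np.isnan(s)
        if mask is not None:
            valid = valid & np.asarray(mask.values, dtype=bool)
        if not valid.any():
            raise ProjectionError("no valid cells for MESS summary")
        return float((s[valid] < 0).sum() / valid.sum())


def mess(
    grids: dict[str, xr.DataArray], reference_points: dict[str, np.ndarray]
) -> MESSSurface:
    """Multivariate environmental similarity surface over all predictor grids.

    Per cell: the minimum single-variable similarity, and which variable
    attains it (the most-dissimilar variable).
    """
    names = tuple(grids)
    if not names:
        raise ProjectionError("at least one predictor grid required")
    missing = [n for n in names if n not in reference_points]
    if missing:
        raise ProjectionError(f"missing reference points for: {missing}")
    arrays = list(grids.values())
    for other in arrays[1:]:
        _check_geometry(arrays[0], other)
    sims = np.stack(
        [mess_similarity(grids[n].values, reference_points[n]) for n in names]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # masked cells are all-NaN
        min_sim = np.nanmin(sims, axis=0)
    argmin = np.argmin(
        np.where(np.isnan(sims), np.inf, sims), axis=0
    ).astype(float)
    masked = np.isnan(arrays[0].values)
    min_sim = np.where(masked, np.nan, min_sim)
    argmin = np.where(masked, np.nan, argmin)
    coords, dims = arrays[0].coords, arrays[0].dims
    return MESSSurface(
        similarity=xr.DataArray(min_sim, coords=coords, dims=dims),
        most_dissimilar=xr.DataArray(argmin, coords=coords, dims=dims),
        variable_names=names,
    )


def project_report(
    model: FittedNicheModel,
    tau: float,
    baseline: dict[str, xr.DataArray],
    scenarios: dict[float, dict[str, dict[str, xr.DataArray]]],
    reference_points: dict[str, np.ndarray],
    lat_min: float = DEFAULT_REGION["lat_min"],
    lon_min: float = DEFAULT_REGION["lon_min"],
) -> pd.DataFrame:
    """Summary table across warming levels and ensemble members.

    ``scenarios`` maps warming level -> member label -> predictor grids.
    The baseline row is reported at the preindustrial offset of its period
    (member 'baseline'). Columns: warming_X, member, fraction,
    northern_limit_lat, shift_km, mess_negative_fraction; plus per-level
    min/max fraction across members.
    """
    any_grid = next(iter(baseline.values()))
    mask = region_mask(any_grid, lat_min, lon_min)

    def one(grids: dict[str, xr.DataArray]) -> tuple[float, float | None, float]:
        prob = predict_grid(model, grids)
        habitat = threshold_map(prob, tau)
        frac = habitat_fraction(habitat, mask)
        limit = northern_limit(habitat, mask)
        neg = mess(grids, reference_points).negative_fraction(mask)
        return frac, limit, neg

    rows = []
    base_frac, base_limit, base_neg = one(baseline)
    rows.append(
        {
            "warming_X": 0.5,
            "member": "baseline",
            "fraction": base_frac,
            "northern_limit_lat": base_limit,
            "shift_km": 0.0,
            "mess_negative_fraction": base_neg,
        }
    )
    for level in sorted(scenarios):
        for member, grids in scenarios[level].items():
            frac, limit, neg = one(grids)
            shift = (
                northward_shift(base_limit, limit)
                if base_limit is not None and limit is not None
                else np.nan
            )
            rows.append(
                {
                    "warming_X": level,
                    "member": member,
                    "fraction": frac,
                    "northern_limit_lat": limit,
                    "shift_km": shift,
                    "mess_negative_fraction": neg,
                }
            )
    table = pd.DataFrame(rows)
    ranges = (
        table.groupby("warming_X")["fraction"].agg(["min", "max"]).rename(
            columns={"min": "fraction_min", "max": "fraction_max"}
        )
    )
    return table.merge(ranges, on="warming_X")
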