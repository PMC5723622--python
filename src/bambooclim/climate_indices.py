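"""Kira-style climatic indices from monthly station climatologies.

The predictors used throughout the pipeline are derived from twelve monthly
mean temperatures and precipitation totals per station: the warmth index
(WI, annual sum of positive excesses of monthly mean temperature over +5°C),
the coldness index (CI, annual sum of the negative deficits, stored as a
non-positive number), and the split of annual precipitation into growing
(months with mean temperature >= 5°C) and non-growing season totals.

WI and CI always satisfy ``WI + CI = 12 * (mean monthly temperature - 5)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

GROWING_SEASON_BASE_C = 5.0
MONTHS_PER_YEAR = 12


class ClimatologyError(ValueError):
    """Raised for structurally invalid climatology input."""


def _as_monthly(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (MONTHS_PER_YEAR,):
        raise ClimatologyError(
            f"{name} must have exactly {MONTHS_PER_YEAR} monthly values, "
            f"got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ClimatologyError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class MonthlyClimatology:
    """One station's monthly climatology plus annual temperature extremes.

    ``annual_min_temp``/``annual_max_temp`` are the yearly extreme hourly
    temperatures and are consumed as provided columns; they are not derivable
    from monthly means.
    """

    station_id: str
    monthly_mean_temp: tuple[float, ...]
    monthly_precip: tuple[float, ...]
    annual_min_temp: float
    annual_max_temp: float
    sun_radiation: float  # MJ m^-2 day^-1

    def __post_init__(self) -> None:
        t = _as_monthly(self.monthly_mean_temp, "monthly_mean_temp")
        p = _as_monthly(self.monthly_precip, "monthly_precip")
        if np.any(p < 0):
            raise ClimatologyError("monthly_precip must be non-negative")
        if self.annual_min_temp > t.min() + 1e-9:
            raise ClimatologyError(
                "annual_min_temp exceeds the coldest monthly mean"
            )
        if self.annual_max_temp < t.max() - 1e-9:
            raise ClimatologyError(
                "annual_max_temp is below the warmest monthly mean"
            )
        object.__setattr__(self, "monthly_mean_temp", tuple(float(x) for x in t))
        object.__setattr__(self, "monthly_precip", tuple(float(x) for x in p))


@dataclass(frozen=True)
class ClimatologySummary:
    """Derived climatic predictors for one station (one averaging window)."""

    mean_annual_temp: float
    warmth_index: float  # °C·month, >= 0
    coldness_index: float  # °C·month, <= 0
    annual_precip: float
    growing_precip: float
    nongrowing_precip: float
    sun_radiation: float
    annual_min_temp: float
    annual_max_temp: float


def warmth_index(monthly_mean_temp: Sequence[float]) -> float:
    """Annual sum of positive differences between monthly mean temperature and +5°C."""
    t = _as_monthly(monthly_mean_temp, "monthly_mean_temp")
    return float(np.sum(np.maximum(t - GROWING_SEASON_BASE_C, 0.0)))


def coldness_index(monthly_mean_temp: Sequence[float]) -> float:
    """Annual sum of negative differences against +5°C; non-positive by convention."""
    t = _as_monthly(monthly_mean_temp, "monthly_mean_temp")
    return float(np.sum(np.minimum(t - GROWING_SEASON_BASE_C, 0.0)))


def seasonal_precip_split(
    monthly_mean_temp: Sequence[float], monthly_precip: Sequence[float]
) -> tuple[float, float]:
    """Split annual precipitation into growing (monthly mean >= 5°C, inclusive)
    and non-growing season totals. Conserves the annual total exactly."""
    t = _as_monthly(monthly_mean_temp, "monthly_mean_temp")
    p = _as_monthly(monthly_precip, "monthly_precip")
    if np.any(p < 0):
        raise ClimatologyError("monthly_precip must be non-negative")
    growing_mask = t >= GROWING_SEASON_BASE_C
    growing = float(p[growing_mask].sum())
    nongrowing = float(p[~growing_mask].sum())
    return growing, nongrowing


def summarize(clim: MonthlyClimatology) -> ClimatologySummary:
    """All derived predictors for a single-year (or pre-averaged) climatology."""
    t = np.asarray(clim.monthly_mean_temp)
    growing, nongrowing = seasonal_precip_split(
        clim.monthly_mean_temp, clim.monthly_precip
    )
    return ClimatologySummary(
        mean_annual_temp=float(t.mean()),
        warmth_index=warmth_index(clim.monthly_mean_temp),
        coldness_index=coldness_index(clim.monthly_mean_temp),
        annual_precip=float(np.sum(clim.monthly_precip)),
        growing_precip=growing,
        nongrowing_precip=nongrowing,
        sun_radiation=clim.sun_radiation,
        annual_min_temp=clim.annual_min_temp,
        annual_max_temp=clim.annual_max_temp,
    )


def summarize_window(per_year: Sequence[MonthlyClimatology]) -> ClimatologySummary:
    """Average the derived predictors over a multi-year window.

    Indices are computed per year and then averaged (not computed on the
    averaged monthly climatology): WI is convex in temperature, so the two
    orders differ in general; this order matches per-year averaging of
    climatic variables over windows such as 1979-1988 or 2002-2011.
    """
    if not per_year:
        raise ClimatologyError("empty climatology window")
    summaries = [summarize(c) for c in per_year]

    def avg(attr: str) -> float:
        return float(np.mean([getattr(s, attr) for s in summaries]))

    return ClimatologySummary(
        mean_annual_temp=avg("mean_annual_temp"),
        warmth_index=avg("warmth_index"),
        coldness_index=avg("coldness_index"),
        annual_precip=avg("annual_precip"),
        growing_precip=avg("growing_precip"),
        nongrowing_precip=avg("nongrowing_precip"),
        sun_radiation=avg("sun_radiation"),
        annual_min_temp=avg("annual_min_temp"),
        annual_max_temp=avg("annual_max_temp"),
    )
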