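"""Detrended monthly anomalies and decadal annual-cycle climatologies.

The seasonal analysis works with "primed" quantities: monthly anomalies
relative to the annual mean, after removing the secular trend.  The trend at
each grid cell is a cubic spline through the per-year annual means, placed at
each year's mean month-midpoint position on a 365-day no-leap calendar and
evaluated at the month midpoints; subtracting it leaves anomalies whose
per-year means vanish exactly for a linear trend and to high order otherwise.
A smoothing parameter turns the interpolating spline into a smoothing spline
when interannual noise in the annual means should be suppressed.

Decadal climatologies average the anomalies month-wise over a decade and are
re-centred so the twelve values sum to zero by construction — the defining
property of an anomaly relative to the annual mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, make_smoothing_spline

__all__ = [
    "MonthlyTimeSeries",
    "AnnualCycleClimatology",
    "MONTH_MIDPOINTS",
    "SUMMER_JAS_SPLIT",
    "SUMMER_JJA",
    "detrend_values",
    "detrend_monthly_series",
    "decadal_climatology",
    "summer_anomaly",
]

_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)
_CUM = np.concatenate([[0.0], np.cumsum(_DAYS)])
#: month midpoints as year fractions, 365-day climatological calendar
MONTH_MIDPOINTS = (_CUM[:-1] + _DAYS / 2.0) / 365.0

#: default summer window: June, August, September (the split convention used
#: for summer-anomaly maps); JJA is the contiguous alternative
SUMMER_JAS_SPLIT = frozenset({6, 8, 9})
SUMMER_JJA = frozenset({6, 7, 8})


@dataclass
class MonthlyTimeSeries:
    """Monthly values on a (year, month) grid, contiguous years, no gaps."""

    values: np.ndarray  # (nyears, 12, ...) trailing dims optional
    years: np.ndarray  # (nyears,) contiguous integers

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        if self.values.ndim < 2 or self.values.shape[1] != 12:
            raise ValueError("values must have shape (nyears, 12, ...)")
        if self.values.shape[0] != self.years.size:
            raise ValueError("years length does not match values")
        if self.years.size > 1 and np.any(np.diff(self.years) != 1):
            raise ValueError("years must be contiguous")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("missing months are not supported")


@dataclass
class AnnualCycleClimatology:
    """Twelve monthly anomalies (zero mean) for one decade, plus annual mean."""

    anomalies: np.ndarray  # (12,)
    annual_mean: float
    decade: tuple[int, int]

    def __post_init__(self) -> None:
        self.anomalies = np.asarray(self.anomalies, dtype=float)
        if self.anomalies.shape != (12,):
            raise ValueError("anomalies must have shape (12,)")


def detrend_values(
    values: np.ndarray, years: np.ndarray, lam: float | None = None
) -> np.ndarray:
    """Remove a cubic-spline secular trend from (nyears, 12, ...) values.

    The spline is fit to per-year annual means; `lam` is the smoothing
    penalty of a cubic smoothing spline (None = interpolating natural
    spline).  Works on trailing spatial dimensions in one pass.
    """
    values = np.asarray(values, dtype=float)
    years = np.asarray(years, dtype=float)
    if years.size < 4:
        raise ValueError("detrending needs at least 4 years of data")
    annual = values.mean(axis=1)  # (nyears, ...)
    # knot abscissae: each year's mean month-midpoint (equal-weight months)
    x_knots = years + MONTH_MIDPOINTS.mean()
    x_eval = (years[:, None] + MONTH_MIDPOINTS[None, :]).ravel()
    if lam is None:
        spl = CubicSpline(x_knots, annual, axis=0, bc_type="natural")
        trend = spl(x_eval)
    else:
        flat = annual.reshape(years.size, -1)
        cols = [make_smoothing_spline(x_knots, col, lam=lam)(x_eval) for col in flat.T]
        trend = np.stack(cols, axis=-1).reshape((x_eval.size,) + annual.shape[1:])
    trend = trend.reshape((years.size, 12) + values.shape[2:])
    return values - trend


def detrend_monthly_series(
    series: MonthlyTimeSeries, lam: float | None = None
) -> MonthlyTimeSeries:
    """Detrended monthly anomalies of a series (same shape, trend removed)."""
    return MonthlyTimeSeries(
        values=detrend_values(series.values, series.years, lam=lam),
        years=series.years,
    )


def decadal_climatology(
    anomalies: MonthlyTimeSeries,
    decade: tuple[int, int],
    raw: MonthlyTimeSeries | None = None,
) -> AnnualCycleClimatology:
    """Month-wise mean of anomalies over a decade, re-centred to zero mean.

    `raw` (the undetrended series) supplies the stored annual mean; without
    it the annual mean is reported as 0.
    """
    y0, y1 = decade
    sel = (anomalies.years >= y0) & (anomalies.years <= y1)
    if sel.sum() != y1 - y0 + 1:
        raise ValueError(f"decade {decade} not fully covered by series")
    clim = anomalies.values[sel].mean(axis=0)
    clim = clim - clim.mean(axis=0)
    annual_mean = 0.0
    if raw is not None:
        rsel = (raw.years >= y0) & (raw.years <= y1)
        if rsel.sum() != y1 - y0 + 1:
            raise ValueError(f"decade {decade} not fully covered by raw series")
        annual_mean = float(raw.values[rsel].mean())
    if clim.ndim != 1:
        raise ValueError("decadal_climatology expects a single-cell series")
    return AnnualCycleClimatology(anomalies=clim, annual_mean=annual_mean, decade=(y0, y1))


def summer_anomaly(
    clim: AnnualCycleClimatology, summer_months=SUMMER_JAS_SPLIT
) -> float:
    """Arithmetic mean of the climatology's anomalies over the summer window."""
    months = sorted(summer_months)
    if not months or any(m < 1 or m > 12 for m in months):
        raise ValueError("summer_months must be a nonempty subset of 1..12")
    return float(np.mean([clim.anomalies[m - 1] for m in months]))
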