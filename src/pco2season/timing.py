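"""Phenology of the annual cycle: timing of highs and lows, crossover, stages.

As atmospheric CO2 rises, the month of the basin-mean annual high of pCO2'
can migrate from late winter into summer while the annual low retreats the
other way; the CO2 level at which the summer extreme first becomes the
annual maximum is the crossover.  The seasonal-cycle shape passes through
three stages on the way: (1) no summer maximum, (2) a positive secondary
summer maximum, (3) the annual maximum in summer.

Months live on a circle: timing series are unwrapped to a continuous branch
before spline smoothing so a Dec->Jan migration does not alias as an
eleven-month jump.  Sea-ice retreat and growth dates use the 0.15
concentration threshold; cells that never cross it carry no date and are
excluded from area-weighted mean timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .grid import area_weighted_mean

__all__ = [
    "ExtremeMonths",
    "IceDates",
    "TimingCurve",
    "CrossoverPoint",
    "ICE_THRESHOLD",
    "extreme_months",
    "ice_transition_dates",
    "stage_classify",
    "stage_sequence",
    "build_timing_curve",
    "detect_crossover",
    "debias_summer_max",
]

ICE_THRESHOLD = 0.15


@dataclass(frozen=True)
class ExtremeMonths:
    """Months (1-12) of the annual high and low; degenerate if the cycle is flat."""

    high: int | None
    low: int | None
    degenerate: bool = False


def extreme_months(monthly_means, rtol: float = 1e-12) -> ExtremeMonths:
    """Months of the annual maximum and minimum of 12 basin-mean values.

    Ties break to the earliest month.  An all-equal cycle yields an explicit
    degenerate result rather than an arbitrary month.
    """
    v = np.asarray(monthly_means, dtype=float)
    if v.shape != (12,) or not np.all(np.isfinite(v)):
        raise ValueError("expected 12 finite monthly values")
    span = v.max() - v.min()
    scale = max(np.abs(v).max(), 1.0)
    if span <= rtol * scale:
        return ExtremeMonths(high=None, low=None, degenerate=True)
    return ExtremeMonths(high=int(np.argmax(v)) + 1, low=int(np.argmin(v)) + 1)


@dataclass
class IceDates:
    """Per-cell ice retreat/growth months and their area-weighted means."""

    retreat: np.ndarray  # month 1-12 or nan (no retreat)
    growth: np.ndarray
    mean_retreat: float
    mean_growth: float
    late_summer_transition: np.ndarray = field(default=None)  # retreat <= July


def ice_transition_dates(ice_conc, areas, threshold: float = ICE_THRESHOLD) -> IceDates:
    """Sea-ice retreat and growth months from monthly concentration fields.

    `ice_conc` has shape (12, ...) with concentrations in [0, 1].  Retreat is
    the first month the concentration drops below the threshold (coming from
    at or above it, circularly); growth is the first month it rises back to
    or above the threshold.  Cells that never cross in either direction get
    nan and are excluded from the area-weighted mean month indices.
    """
    c = np.asarray(ice_conc, dtype=float)
    if c.shape[0] != 12:
        raise ValueError("ice concentration must have a leading 12-month axis")
    if np.any(c < -1e-9) or np.any(c > 1 + 1e-9):
        raise ValueError("ice concentrations must lie in [0, 1]")
    below = c < threshold
    prev = np.roll(below, 1, axis=0)
    retreat_hit = below & ~prev  # first month below after a month at/above
    growth_hit = ~below & prev
    shape = c.shape[1:]
    retreat = np.full(shape, np.nan)
    growth = np.full(shape, np.nan)
    for m in range(11, -1, -1):  # earliest crossing wins
        retreat = np.where(retreat_hit[m], m + 1, retreat)
        growth = np.where(growth_hit[m], m + 1, growth)
    areas = np.asarray(areas, dtype=float)

    def _mean(months):
        ok = np.isfinite(months)
        if not ok.any():
            return float("nan")
        return float(area_weighted_mean(np.where(ok, months, 0.0), ok, areas))

    return IceDates(
        retreat=retreat,
        growth=growth,
        mean_retreat=_mean(retreat),
        mean_growth=_mean(growth),
        late_summer_transition=retreat <= 7,
    )


def stage_classify(anomalies, summer_window) -> int:
    """Classify a 12-month anomaly cycle into the three timing stages.

    3 — the annual maximum falls inside the summer window; 2 — a positive
    local (circular) maximum exists inside the window; 1 — neither.
    """
    v = np.asarray(anomalies, dtype=float)
    if v.shape != (12,):
        raise ValueError("expected 12 monthly anomalies")
    window = sorted(summer_window)
    ext = extreme_months(v)
    if ext.degenerate:
        return 1
    if ext.high in window:
        return 3
    for m in window:
        i = m - 1
        if v[i] > 0 and v[i] >= v[(i - 1) % 12] and v[i] >= v[(i + 1) % 12]:
            return 2
    return 1


@dataclass
class TimingCurve:
    """Month of annual high/low versus atmospheric CO2, raw and smoothed.

    Month indices are real-valued on a circular topology; the smoothed
    curves are cubic-spline fits of the phase-unwrapped raw points mapped
    back into [1, 13).
    """

    co2_levels: np.ndarray
    month_of_high: np.ndarray  # raw, 1-12
    month_of_low: np.ndarray
    smooth_high: np.ndarray = None  # smoothed, in [1, 13)
    smooth_low: np.ndarray = None


def _unwrap_months(months) -> np.ndarray:
    phase = (np.asarray(months, dtype=float) - 1.0) * (2.0 * np.pi / 12.0)
    return np.unwrap(phase) * (12.0 / (2.0 * np.pi)) + 1.0


def _smooth(levels, series, lam) -> np.ndarray:
    if len(levels) < 4 or lam is None:
        return np.asarray(series, dtype=float)
    spl = make_smoothing_spline(np.asarray(levels, float), np.asarray(series, float), lam=lam)
    return spl(np.asarray(levels, float))


def build_timing_curve(co2_levels, climatologies, lam: float | None = 1e4) -> TimingCurve:
    """Timing of the annual high/low at each CO2 level, spline-smoothed.

    `climatologies` is an (nlevels, 12) array of basin-mean anomaly cycles.
    Smoothing suppresses interannual flicker in the raw month indices.
    """
    levels = np.asarray(co2_levels, dtype=float)
    if np.any(np.diff(levels) <= 0):
        raise ValueError("CO2 levels must be strictly increasing")
    clim = np.atleast_2d(np.asarray(climatologies, dtype=float))
    highs, lows = [], []
    for row in clim:
        ext = extreme_months(row)
        if ext.degenerate:
            raise ValueError("degenerate (flat) cycle in timing curve input")
        highs.append(ext.high)
        lows.append(ext.low)
    uh = _unwrap_months(highs)
    ul = _unwrap_months(lows)
    sh = (_smooth(levels, uh, lam) - 1.0) % 12.0 + 1.0
    sl = (_smooth(levels, ul, lam) - 1.0) % 12.0 + 1.0
    return TimingCurve(
        co2_levels=levels,
        month_of_high=np.asarray(highs, float),
        month_of_low=np.asarray(lows, float),
        smooth_high=sh,
        smooth_low=sl,
    )


@dataclass(frozen=True)
class CrossoverPoint:
    """Atmospheric CO2 level (ppm) and month at which the summer extreme
    first becomes the annual maximum."""

    co2_ppm: float
    month: int


def _smooth_climatologies(levels, clim, lam) -> np.ndarray:
    """Smooth each month's anomaly across CO2 levels (suppresses noise)."""
    levels = np.asarray(levels, dtype=float)
    clim = np.asarray(clim, dtype=float)
    if lam is None or levels.size < 4:
        return clim
    out = np.empty_like(clim)
    for m in range(12):
        out[:, m] = make_smoothing_spline(levels, clim[:, m], lam=lam)(levels)
    return out


def stage_sequence(co2_levels, climatologies, summer_window, lam: float | None = 1e4):
    """Stage (1/2/3) at each CO2 level after smoothing across levels."""
    levels = np.asarray(co2_levels, dtype=float)
    if np.any(np.diff(levels) <= 0):
        raise ValueError("CO2 levels must be strictly increasing")
    clim = _smooth_climatologies(levels, np.atleast_2d(climatologies), lam)
    return np.array([stage_classify(row, summer_window) for row in clim])


def detect_crossover(
    co2_levels,
    climatologies,
    summer_window,
    lam: float | None = 1e4,
) -> CrossoverPoint | None:
    """Lowest CO2 level at which the smoothed cycle reaches stage 3.

    Equivalent to the annual high/low timing curves crossing where both are
    well defined, but remains robust when the low is indistinct.  Returns
    None if stage 3 is never reached (some trajectories do not cross within
    their scenario).  Invariant to adding a constant to every climatology.
    """
    levels = np.asarray(co2_levels, dtype=float)
    if levels.size < 3:
        raise ValueError("need at least 3 CO2 levels")
    if np.any(np.diff(levels) <= 0):
        raise ValueError("CO2 levels must be strictly increasing")
    clim = np.atleast_2d(np.asarray(climatologies, dtype=float))
    clim = clim - clim.mean(axis=1, keepdims=True)  # shift-invariance guard
    smoothed = _smooth_climatologies(levels, clim, lam)
    window = sorted(summer_window)
    for i, row in enumerate(smoothed):
        if stage_classify(row, window) == 3:
            high = extreme_months(row).high
            return CrossoverPoint(co2_ppm=float(levels[i]), month=int(high))
    return None


def debias_summer_max(
    model_clim_hist, obs_clim, model_clim_future, shelf_mask, areas
) -> float:
    """Debiased area-mean annual maximum (e.g. of SST) over shelf cells.

    The per-cell, per-month model bias (historical climatology minus the
    observational climatology) is removed from the future climatology; the
    per-cell annual maximum of the debiased field is then area-averaged over
    the shelf mask.
    """
    hist = np.asarray(model_clim_hist, dtype=float)
    obs = np.asarray(obs_clim, dtype=float)
    fut = np.asarray(model_clim_future, dtype=float)
    if hist.shape != obs.shape or hist.shape != fut.shape or hist.shape[0] != 12:
        raise ValueError("climatologies must share a (12, ...) shape")
    mask = np.asarray(shelf_mask, dtype=bool)
    if not mask.any():
        raise ValueError("shelf mask is empty")
    debiased = fut - (hist - obs)
    annual_max = debiased.max(axis=0)
    return float(area_weighted_mean(annual_max, mask, np.asarray(areas, float)))
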