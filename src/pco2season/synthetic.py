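"""Seeded generator of ESM-like monthly surface fields for a polar ocean.

The generator emulates the statistical structure the seasonal-timing
analysis assumes, without any ocean dynamics:

* sinusoid-like seasonal cycles of temperature, salinity, alkalinity and DIC,
  with a biologically phased summer DIC drawdown tied to an NPP forcing
  curve;
* seasonal sea-ice cover diagnosed from monthly temperature against a
  latitude-dependent freezing threshold, so the retreat date advances as the
  water warms;
* summer-amplified warming where ice retreats earlier (a Gaussian summer
  bump proportional to the retreat advance), the mechanism that eventually
  flips the summer pCO2' low into a high;
* a secular DIC trend expressed as a fixed airborne-fraction-style coupling
  to the atmospheric CO2 pathway (no air-sea flux model — the analysis only
  needs realistic driver trajectories);
* ice-melt freshening that dilutes salinity, alkalinity and DIC
  conservatively;
* optional Gaussian noise per field, fully reproducible from one seed.

A TruthRecord built from the noise-free construction (direct carbonate
solves of the exact basin-mean drivers, no detrending or smoothing) stores
the constructed crossover CO2 level, retreat dates and decade summaries, so
pipeline estimates can be scored against a known answer.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import xarray as xr

from .carbonate import solve_arrays
from .grid import GridSpec, area_weighted_mean

__all__ = [
    "ScenarioConfig",
    "EmulatorParams",
    "TruthRecord",
    "co2_pathway",
    "generate_fields",
    "DEFAULT_SUMMER_WINDOW",
]

DEFAULT_SUMMER_WINDOW = (6, 7, 8, 9)
_MONTHS = np.arange(1, 13, dtype=float)


@dataclass(frozen=True)
class ScenarioConfig:
    """Atmospheric CO2 pathway: idealized 1%/yr, RCP-like ramp, or flat."""

    kind: str = "rcp_like"  # one_percent | rcp_like | flat
    start_ppm: float = 284.0
    start_year: int = 1950
    years: int = 151
    # rcp_like ramp ppm(t) = start + a (exp(r (year - 1850)) - 1); defaults
    # track the historical record (~313 ppm in 1950) and reach ~936 ppm in 2100
    ramp_a: float = 4.65
    ramp_r: float = 0.0198

    def __post_init__(self) -> None:
        if self.kind not in ("one_percent", "rcp_like", "flat"):
            raise ValueError(f"unknown pathway kind {self.kind!r}")
        if self.start_ppm <= 0 or self.years < 1:
            raise ValueError("pathway needs positive start_ppm and years >= 1")


def co2_pathway(config: ScenarioConfig) -> np.ndarray:
    """Annual atmospheric CO2 series (ppm) for a scenario."""
    i = np.arange(config.years, dtype=float)
    if config.kind == "one_percent":
        return config.start_ppm * 1.01**i
    if config.kind == "flat":
        return np.full(config.years, config.start_ppm)
    t = (config.start_year - 1850) + i
    return config.start_ppm + config.ramp_a * (np.exp(config.ramp_r * t) - 1.0)


@dataclass(frozen=True)
class EmulatorParams:
    """Couplings and amplitudes of the synthetic polar surface ocean.

    Amplitudes are typical Arctic-surface magnitudes; couplings are linear
    with physical clamps.  All fields stay inside the carbonate solver's
    valid ranges after generation.
    """

    # mean state and seasonal cycles; the small base SST amplitude reflects
    # ice cover pinning surface temperature near freezing most of the year —
    # large summer warming only appears once ice retreats earlier (the bump)
    t_mean: float = 0.5  # degC at the cap edge
    t_lat_gradient: float = -0.06  # degC per degree poleward
    t_seasonal_amp: float = 1.0  # degC, maximum in August
    t_peak_month: float = 8.0
    s_base: float = 33.0
    at_base: float = 2230.0  # µmol kg-1 at S = s_base
    ct_preindustrial: float = 2080.0  # µmol kg-1 annual mean at 284 ppm
    # secular couplings
    warming_per_doubling: float = 2.5  # degC per CO2 doubling (polar surface)
    ct_trend_coupling: float = 0.20  # µmol kg-1 per ppm of atmospheric rise
    # ice
    ice_freeze_offset: float = 1.0  # degC threshold at the cap edge
    ice_freeze_lat_gradient: float = 0.15  # degC per degree poleward
    ice_width: float = 0.5  # degC, sharpness of the cover transition
    # couplings that reshape summer: extra summer warming scales with the
    # increase in pre-August open-water fraction (solar heating of open
    # water), which is what earlier ice retreat exposes
    summer_warming_gain: float = 5.0  # degC per unit open-water increase
    summer_bump_month: float = 7.5
    summer_bump_width: float = 1.5
    bio_drawdown: float = 20.0  # µmol kg-1 per unit cumulative bloom uptake
    npp_base: float = 0.05  # relative units
    npp_amp: float = 1.0
    npp_peak_month: float = 7.0
    npp_width: float = 1.5
    npp_advance: float = 0.5  # months of earlier bloom per month earlier retreat
    melt_dilution: float = 0.8  # salinity drop per unit ice fraction melted
    # noise (1 s.d. per field per month per cell)
    noise_t: float = 0.15
    noise_s: float = 0.05
    noise_at: float = 4.0
    noise_ct: float = 4.0
    noise_ice: float = 0.02
    noise_npp: float = 0.05
    seed: int = 0


@dataclass
class TruthRecord:
    """Constructed (noise-free) answers the pipeline should recover."""

    crossover_ppm: float | None
    crossover_year: int | None
    retreat_month_modern: float
    retreat_month_future: float
    summer_t_anomaly_modern: float
    summer_t_anomaly_future: float
    summer_ct_anomaly_modern: float
    summer_ct_anomaly_future: float
    modern_decade: tuple[int, int]
    future_decade: tuple[int, int]
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _retreat_months(conc: np.ndarray) -> np.ndarray:
    """First month below 0.15 coming from at/above it (nan if never)."""
    below = conc < 0.15
    prev = np.roll(below, 1, axis=0)
    hit = below & ~prev
    out = np.full(conc.shape[1:], np.nan)
    for m in range(conc.shape[0] - 1, -1, -1):
        out = np.where(hit[m], m + 1, out)
    return out


def _construct(params: EmulatorParams, ppm: np.ndarray, grid: GridSpec, rng):
    """Deterministic construction of all fields; rng=None means noise-free."""
    p = params
    nyears = ppm.size
    lat2d = np.broadcast_to(grid.lat[:, None], (grid.lat.size, grid.lon.size))
    m = _MONTHS[None, :, None, None]  # (1, 12, 1, 1)
    yshape = (nyears, 12) + lat2d.shape

    t_mean0 = p.t_mean + p.t_lat_gradient * (lat2d - grid.lat.min())
    warming = p.warming_per_doubling * np.log2(ppm / ppm[0])
    seasonal = p.t_seasonal_amp * np.cos(2 * np.pi * (m - p.t_peak_month) / 12.0)
    t0 = t_mean0[None, None] + warming[:, None, None, None] + seasonal
    t0 = np.maximum(t0, -1.9)  # sea water cannot cool below freezing

    thresh = p.ice_freeze_offset + p.ice_freeze_lat_gradient * (lat2d - grid.lat.min())
    ice0 = 1.0 / (1.0 + np.exp(-(thresh[None, None] - t0) / p.ice_width))

    retreat0 = np.stack([_retreat_months(ice0[y]) for y in range(nyears)])
    # cells starting with perennial ice count a transition to seasonal ice
    # as a retreat from just past the year's end
    ref = np.where(np.isfinite(retreat0[0]), retreat0[0], 12.5)
    advance = np.where(np.isfinite(retreat0), ref[None] - retreat0, 0.0)
    advance = np.clip(advance, 0.0, None)
    # open-water fraction March-August, relative to the first year
    exposure = (1.0 - ice0[:, 2:8]).mean(axis=1)
    exposure = np.clip(exposure - exposure[0][None], 0.0, None)
    bump = np.exp(-0.5 * ((m - p.summer_bump_month) / p.summer_bump_width) ** 2)
    t = t0 + p.summer_warming_gain * exposure[:, None] * bump
    t = np.clip(t, -1.9, 39.9)

    ice = 1.0 / (1.0 + np.exp(-(thresh[None, None] - t) / p.ice_width))

    # the bloom peak advances where ice retreats earlier; amplitude is fixed
    peak = p.npp_peak_month - p.npp_advance * advance[:, None]
    bloom = np.exp(-0.5 * ((m - peak) / p.npp_width) ** 2)
    npp = p.npp_base + p.npp_amp * bloom

    melt = np.clip(np.roll(ice, 1, axis=1) - ice, 0.0, None)
    s = p.s_base - p.melt_dilution * melt
    dilution = s / p.s_base
    at = p.at_base * dilution
    # DIC: secular trend tracking the pathway, conservative dilution, and a
    # bloom-drawdown/winter-resupply cycle — the cumulative sum of NPP in
    # excess of its annual mean, so DIC peaks just before the bloom and
    # bottoms out just after it
    ct_mean = p.ct_preindustrial + p.ct_trend_coupling * (ppm - 284.0)
    uptake = npp / max(p.npp_amp, 1e-12)
    deficit = np.cumsum(uptake - uptake.mean(axis=1, keepdims=True), axis=1)
    deficit = deficit - deficit.mean(axis=1, keepdims=True)
    ct = ct_mean[:, None, None, None] * dilution - p.bio_drawdown * deficit

    if rng is not None:
        t = np.clip(t + rng.normal(0, p.noise_t, yshape), -1.9, 39.9)
        s = np.clip(s + rng.normal(0, p.noise_s, yshape), 20.0, 40.0)
        at = np.clip(at + rng.normal(0, p.noise_at, yshape), 0.0, None)
        ct = np.clip(ct + rng.normal(0, p.noise_ct, yshape), 0.0, None)
        ice = np.clip(ice + rng.normal(0, p.noise_ice, yshape), 0.0, 1.0)
        npp = np.clip(npp + rng.normal(0, p.noise_npp, yshape), 0.0, None)

    for name, arr in (("T", t), ("S", s), ("AT", at), ("CT", ct)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"synthetic field {name} contains non-finite values")
    return {"T": t, "S": s, "AT": at, "CT": ct, "ice": ice, "NPP": npp}


def _basin_series(fields: dict, grid: GridSpec) -> dict:
    """Area-weighted domain means, (nyears, 12) per field."""
    w = (grid.cell_area * grid.domain_mask).ravel()
    w = w / w.sum()
    out = {}
    for name, arr in fields.items():
        flat = arr.reshape(arr.shape[:2] + (-1,))
        out[name] = flat @ w
    return out


def _truth_record(
    params: EmulatorParams,
    scenario: ScenarioConfig,
    grid: GridSpec,
    ppm: np.ndarray,
    summer_window=DEFAULT_SUMMER_WINDOW,
) -> TruthRecord:
    clean = _construct(params, ppm, grid, rng=None)
    basin = _basin_series(clean, grid)
    sol = solve_arrays(basin["T"], basin["S"], basin["AT"], basin["CT"])
    pco2 = sol["pCO2"]
    prime = pco2 - pco2.mean(axis=1, keepdims=True)
    window = np.array(sorted(summer_window)) - 1
    in_summer = np.zeros(prime.shape[0], dtype=bool)
    for y in range(prime.shape[0]):
        in_summer[y] = int(np.argmax(prime[y])) in window
    crossover_year = None
    crossover_ppm = None
    for y in range(prime.shape[0]):
        if in_summer[y:].all() and in_summer[y]:
            crossover_year = int(scenario.start_year + y)
            crossover_ppm = float(ppm[y])
            break

    years = scenario.start_year + np.arange(scenario.years)
    modern = (2006, 2015) if years[0] <= 2006 and years[-1] >= 2015 else (
        int(years[0]), int(years[min(9, years.size - 1)]))
    future = (2091, 2100) if years[-1] >= 2100 else (
        int(years[-1] - 9), int(years[-1]))

    def dec_slice(dec):
        i0 = int(dec[0] - years[0])
        return slice(i0, i0 + (dec[1] - dec[0] + 1))

    def summer_anom(series, dec):
        block = series[dec_slice(dec)].mean(axis=0)
        return float(block[window].mean() - block.mean())

    retreat = {}
    for dec in (modern, future):
        ice_clim = clean["ice"][dec_slice(dec)].mean(axis=0)
        months = _retreat_months(ice_clim)
        ok = np.isfinite(months) & grid.domain_mask
        retreat[dec] = (
            float(area_weighted_mean(np.where(ok, months, 0.0), ok, grid.cell_area))
            if ok.any()
            else float("nan")
        )

    return TruthRecord(
        crossover_ppm=crossover_ppm,
        crossover_year=crossover_year,
        retreat_month_modern=retreat[modern],
        retreat_month_future=retreat[future],
        summer_t_anomaly_modern=summer_anom(basin["T"], modern),
        summer_t_anomaly_future=summer_anom(basin["T"], future),
        summer_ct_anomaly_modern=summer_anom(basin["CT"], modern),
        summer_ct_anomaly_future=summer_anom(basin["CT"], future),
        modern_decade=modern,
        future_decade=future,
        seed=params.seed,
    )


def generate_fields(
    params: EmulatorParams,
    scenario: ScenarioConfig,
    grid: GridSpec,
    summer_window=DEFAULT_SUMMER_WINDOW,
) -> tuple[xr.Dataset, TruthRecord]:
    """Generate monthly surface fields plus the noise-free truth record.

    Returns an xarray Dataset with variables T (degC), S, AT, CT (µmol
    kg-1), ice (fraction) and NPP (relative) on (year, month, lat, lon),
    and the TruthRecord of the same parameterization without noise.
    Regenerating with the same seed reproduces both bit-for-bit.
    """
    ppm = co2_pathway(scenario)
    rng = np.random.default_rng(params.seed)
    fields = _construct(params, ppm, grid, rng)
    truth = _truth_record(params, scenario, grid, ppm, summer_window)
    years = scenario.start_year + np.arange(scenario.years)
    coords = {
        "year": years,
        "month": np.arange(1, 13),
        "lat": grid.lat,
        "lon": grid.lon,
    }
    units = {"T": "degC", "S": "1", "AT": "umol kg-1", "CT": "umol kg-1",
             "ice": "1", "NPP": "relative"}
    ds = xr.Dataset(
        {
            name: (("year", "month", "lat", "lon"), arr, {"units": units[name]})
            for name, arr in fields.items()
        },
        coords=coords,
        attrs={
            "seed": params.seed,
            "pathway": scenario.kind,
            "start_ppm": scenario.start_ppm,
        },
    )
    ds["co2_ppm"] = ("year", ppm)
    return ds, truth
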