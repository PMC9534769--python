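"""End-to-end orchestration: fields -> chemistry -> anomalies -> reports.

One pipeline member takes monthly driver fields (synthetic or loaded from
NetCDF), solves the carbonate system everywhere, detrends, builds decadal
climatologies, runs the Taylor decompositions (standard, freshwater and
incremental layouts), the climate-CO2 separation with summer-enhancement
statistics, and the timing analysis (annual high/low evolution, stage
sequence, crossover, ice dates).  An ensemble of seeded members yields
mean +/- s.d. summaries.  Everything is a pure function of (config, seeds).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xarray as xr

from . import carbonate, seasonal, separation, synthetic, taylor, timing
from .grid import GridSpec, RegionMask, build_masks

__all__ = ["PipelineConfig", "MemberResult", "PipelineResult", "run_pipeline",
           "analyze_dataset"]


@dataclass
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    scenario: synthetic.ScenarioConfig = field(default_factory=synthetic.ScenarioConfig)
    params: synthetic.EmulatorParams = field(default_factory=synthetic.EmulatorParams)
    seeds: tuple = (0,)
    grid_kwargs: dict = field(default_factory=dict)
    modern_decade: tuple = (2006, 2015)
    future_decade: tuple = (2091, 2100)
    summer_window: tuple = synthetic.DEFAULT_SUMMER_WINDOW
    summer_anomaly_months: tuple = tuple(sorted(seasonal.SUMMER_JAS_SPLIT))
    detrend_lam: float | None = None
    timing_lam: float | None = 1e4
    input_path: str | None = None  # NetCDF with the generator's layout
    include_decomposition: bool = True

    def __post_init__(self) -> None:
        years = self.scenario.start_year + np.arange(self.scenario.years)
        if self.input_path is None:
            for dec in (self.modern_decade, self.future_decade):
                if dec[0] < years[0] or dec[1] > years[-1]:
                    raise ValueError(f"decade {dec} outside scenario coverage")
        if not self.seeds:
            raise ValueError("at least one ensemble seed is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "scenario" in raw:
            kwargs["scenario"] = synthetic.ScenarioConfig(**raw.pop("scenario"))
        if "params" in raw:
            kwargs["params"] = synthetic.EmulatorParams(**raw.pop("params"))
        for key in ("seeds", "modern_decade", "future_decade", "summer_window",
                    "summer_anomaly_months"):
            if key in raw:
                raw[key] = tuple(raw[key])
        kwargs.update(raw)
        return cls(**kwargs)


@dataclass
class MemberResult:
    """Everything computed for one ensemble member."""

    seed: int
    co2_levels: np.ndarray  # decade-mean ppm per timing level
    decade_starts: np.ndarray
    basin_climatologies: np.ndarray  # (nlevels, 12) basin-mean pCO2'
    timing_curve: timing.TimingCurve
    stages: np.ndarray
    crossover: timing.CrossoverPoint | None
    truth: synthetic.TruthRecord | None
    modern_terms: taylor.TermSeries | None = None
    modern_terms_fw: taylor.TermSeries | None = None
    future_terms_basic: taylor.TermSeries | None = None
    future_terms_incremental: taylor.TermSeries | None = None
    separation: separation.SeparationResult | None = None
    enhancement_extreme: float | None = None
    enhancement_mean: float | None = None
    ice_dates_modern: timing.IceDates | None = None
    ice_dates_future: timing.IceDates | None = None
    h_pco2_correlation: float | None = None
    temperature_sensitivity_ratio: float | None = None
    shelf_crossover_ppm: float | None = None
    basin_crossover_ppm: float | None = None


@dataclass
class PipelineResult:
    members: list
    summary: dict

    def to_dir(self, outdir) -> None:
        """Write CSV/JSON reports (timing, terms, separation, summary)."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for m in self.members:
            for lev, hi, lo, st in zip(
                m.co2_levels, m.timing_curve.smooth_high,
                m.timing_curve.smooth_low, m.stages,
            ):
                rows.append({"seed": m.seed, "co2_ppm": lev, "high_month": hi,
                             "low_month": lo, "stage": int(st)})
        pd.DataFrame(rows).to_csv(out / "timing.csv", index=False)
        term_rows = []
        for m in self.members:
            for label, ts in (("modern", m.modern_terms),
                              ("modern_fw", m.modern_terms_fw),
                              ("future_basic", m.future_terms_basic),
                              ("future_incremental", m.future_terms_incremental)):
                if ts is None:
                    continue
                for name, arr in ts.terms.items():
                    for mo, v in enumerate(arr, start=1):
                        term_rows.append({"seed": m.seed, "set": label,
                                          "term": name, "month": mo, "uatm": v})
        if term_rows:
            pd.DataFrame(term_rows).to_csv(out / "terms.csv", index=False)
        sep_rows = []
        for m in self.members:
            if m.separation is None:
                continue
            s = m.separation
            for mo in range(12):
                sep_rows.append({
                    "seed": m.seed, "month": mo + 1,
                    "delta_sens": s.delta_sens[mo], "delta_anom": s.delta_anom[mo],
                    "synergy": s.synergy[mo],
                    "delta_anom_star": s.delta_anom_star[mo],
                    "total": s.total[mo],
                })
        if sep_rows:
            pd.DataFrame(sep_rows).to_csv(out / "separation.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, default=float)


def _flat_domain(arr, grid: GridSpec):
    """(..., nlat, nlon) -> (..., ncells) over domain cells."""
    flat = arr.reshape(arr.shape[:-2] + (-1,))
    return flat[..., grid.domain_mask.ravel()]


def _area_weights(grid: GridSpec, mask=None):
    m = grid.domain_mask if mask is None else mask
    w = (grid.cell_area * m).ravel()[grid.domain_mask.ravel()]
    return w / w.sum()


def _decades(years):
    """Consecutive 10-year blocks aligned to end at the final year."""
    last = years[-1]
    starts = np.arange(last - 9, years[0] - 1, -10)[::-1]
    starts = starts[starts >= years[0]]
    return [(int(s), int(s + 9)) for s in starts]


def _decadal_monthly_means(values, years, decade):
    i0 = int(decade[0] - years[0])
    return values[i0 : i0 + (decade[1] - decade[0] + 1)].mean(axis=0)


def _cell_gamma(t, s, at, ct):
    """Basic-approach per-month sensitivities from decadal monthly means.

    Input arrays (12, ncells); returns dict driver -> (12, ncells).
    """
    monthly = carbonate.sensitivity_arrays(t, s, at, ct)
    annual = carbonate.sensitivity_arrays(
        t.mean(axis=0), s.mean(axis=0), at.mean(axis=0), ct.mean(axis=0)
    )
    return {d: 0.5 * (monthly[d] + annual[d][None, :]) for d in taylor.DRIVERS}


def _cell_anoms(t, s, at, ct):
    """Driver anomaly arrays from (12, ncells) decadal monthly means."""
    s0 = s.mean(axis=0)
    sat = at * s0[None, :] / s
    sct = ct * s0[None, :] / s
    return {
        "T": t - t.mean(axis=0),
        "S": s - s0[None, :],
        "AT": at - at.mean(axis=0),
        "CT": ct - ct.mean(axis=0),
        "sAT": sat - sat.mean(axis=0),
        "sCT": sct - sct.mean(axis=0),
        "S0": s0,
        "sAT_mean": sat.mean(axis=0),
        "sCT_mean": sct.mean(axis=0),
    }


def _basin_term_series(anoms, gamma, weights, actual, layout, decade):
    """Area-weighted Taylor decomposition over the domain."""
    if layout == "standard":
        terms = {
            "thermal": gamma["T"] * anoms["T"],
            "haline": gamma["S"] * anoms["S"],
            "alkalinity": gamma["AT"] * anoms["AT"],
            "dic": gamma["CT"] * anoms["CT"],
        }
    else:
        s_month = anoms["S0"][None, :] + anoms["S"]
        ratio = s_month / anoms["S0"][None, :]
        cov_at = (anoms["S"] * anoms["sAT"]).mean(axis=0) / anoms["S0"]
        cov_ct = (anoms["S"] * anoms["sCT"]).mean(axis=0) / anoms["S0"]
        terms = {
            "thermal": gamma["T"] * anoms["T"],
            "haline_direct": gamma["S"] * anoms["S"],
            "fw_alkalinity": gamma["AT"] * (anoms["sAT_mean"] / anoms["S0"])[None, :]
            * anoms["S"],
            "fw_dic": gamma["CT"] * (anoms["sCT_mean"] / anoms["S0"])[None, :]
            * anoms["S"],
            "bio_sAT": gamma["AT"] * (ratio * anoms["sAT"] - cov_at[None, :]),
            "bio_sCT": gamma["CT"] * (ratio * anoms["sCT"] - cov_ct[None, :]),
        }
    basin_terms = {k: v @ weights for k, v in terms.items()}
    return taylor.TermSeries(terms=basin_terms, layout=layout,
                             actual_total=actual, decade=decade)


def analyze_dataset(
    ds: xr.Dataset,
    grid: GridSpec,
    regions: RegionMask,
    config: PipelineConfig,
    truth: synthetic.TruthRecord | None = None,
    seed: int = 0,
) -> MemberResult:
    """Run the full analysis for one member's monthly fields."""
    years = ds["year"].values.astype(int)
    ppm = ds["co2_ppm"].values.astype(float)
    fields = {name: ds[name].values for name in ("T", "S", "AT", "CT", "ice")}
    dom_w = _area_weights(grid)

    cells = {k: _flat_domain(v, grid) for k, v in fields.items()}
    sol = carbonate.solve_arrays(cells["T"], cells["S"], cells["AT"], cells["CT"])
    pco2 = sol["pCO2"]  # (ny, 12, ncells)

    # detrended per-year anomalies relative to each year's annual mean
    def yearly_anoms(values):
        det = seasonal.detrend_values(values, years, lam=config.detrend_lam)
        return det - det.mean(axis=1, keepdims=True)

    p_anom = yearly_anoms(pco2)

    # timing: basin-mean anomaly climatology per decade
    decades = _decades(years)
    levels, clims, starts = [], [], []
    for dec in decades:
        block = _decadal_monthly_means(p_anom, years, dec) @ dom_w
        clims.append(block - block.mean())
        i0 = int(dec[0] - years[0])
        levels.append(ppm[i0 : i0 + 10].mean())
        starts.append(dec[0])
    levels = np.array(levels)
    clims = np.array(clims)
    # a flat pathway has no CO2 axis to evolve along: raw phenology only
    monotone_levels = levels.size > 1 and bool(np.all(np.diff(levels) > 0))
    if monotone_levels:
        curve = timing.build_timing_curve(levels, clims, lam=config.timing_lam)
        stages = timing.stage_sequence(levels, clims, config.summer_window,
                                       lam=config.timing_lam)
        crossover = timing.detect_crossover(levels, clims, config.summer_window,
                                            lam=config.timing_lam)
    else:
        exts = [timing.extreme_months(row) for row in clims]
        highs = np.array([e.high if e.high else np.nan for e in exts], float)
        lows = np.array([e.low if e.low else np.nan for e in exts], float)
        curve = timing.TimingCurve(co2_levels=levels, month_of_high=highs,
                                   month_of_low=lows, smooth_high=highs,
                                   smooth_low=lows)
        stages = np.array([timing.stage_classify(row, config.summer_window)
                           for row in clims])
        crossover = None

    # shelf vs basin crossover (shelf seas flip first)
    def region_crossover(mask):
        if not monotone_levels:
            return None
        w = _area_weights(grid, mask)
        rows = []
        for dec in decades:
            block = _decadal_monthly_means(p_anom, years, dec) @ w
            rows.append(block - block.mean())
        cp = timing.detect_crossover(levels, np.array(rows), config.summer_window,
                                     lam=config.timing_lam)
        return None if cp is None else cp.co2_ppm

    result = MemberResult(
        seed=seed,
        co2_levels=levels,
        decade_starts=np.array(starts),
        basin_climatologies=clims,
        timing_curve=curve,
        stages=stages,
        crossover=crossover,
        truth=truth,
        shelf_crossover_ppm=region_crossover(regions.shelf),
        basin_crossover_ppm=region_crossover(regions.basin),
    )

    # ice transition dates from decadal ice climatologies (full grid)
    for name, dec in (("ice_dates_modern", config.modern_decade),
                      ("ice_dates_future", config.future_decade)):
        clim = _decadal_monthly_means(fields["ice"], years, dec)
        masked = np.where(grid.domain_mask[None], clim, 1.0)
        setattr(result, name,
                timing.ice_transition_dates(masked, grid.cell_area))

    if not config.include_decomposition:
        return result

    # --- decompositions on decadal climatological monthly means, per cell ---
    def decade_state(dec):
        return {k: _decadal_monthly_means(cells[k], years, dec)
                for k in ("T", "S", "AT", "CT")}

    mod, fut = decade_state(config.modern_decade), decade_state(config.future_decade)
    gam0 = _cell_gamma(mod["T"], mod["S"], mod["AT"], mod["CT"])
    gam1 = _cell_gamma(fut["T"], fut["S"], fut["AT"], fut["CT"])
    an0 = _cell_anoms(mod["T"], mod["S"], mod["AT"], mod["CT"])
    an1 = _cell_anoms(fut["T"], fut["S"], fut["AT"], fut["CT"])

    def basin_actual(dec):
        block = _decadal_monthly_means(p_anom, years, dec) @ dom_w
        return block - block.mean()

    actual0, actual1 = basin_actual(config.modern_decade), basin_actual(
        config.future_decade
    )
    result.modern_terms = _basin_term_series(
        an0, gam0, dom_w, actual0, "standard", config.modern_decade
    )
    result.modern_terms_fw = _basin_term_series(
        an0, gam0, dom_w, actual0, "freshwater", config.modern_decade
    )
    result.future_terms_basic = _basin_term_series(
        an1, gam1, dom_w, actual1, "standard", config.future_decade
    )

    # incremental decade-to-decade decomposition, accumulated per cell
    yr_anoms = {
        "T": yearly_anoms(cells["T"]),
        "S": yearly_anoms(cells["S"]),
        "AT": yearly_anoms(cells["AT"]),
        "CT": yearly_anoms(cells["CT"]),
    }
    yr_monthly_gamma = carbonate.sensitivity_arrays(
        cells["T"], cells["S"], cells["AT"], cells["CT"]
    )
    yr_annual_gamma = carbonate.sensitivity_arrays(
        *(cells[k].mean(axis=1) for k in ("T", "S", "AT", "CT"))
    )
    yr_gamma = {
        d: 0.5 * (yr_monthly_gamma[d] + yr_annual_gamma[d][:, None, :])
        for d in taylor.DRIVERS
    }
    inc_terms = {k: v.copy() for k, v in result.modern_terms.terms.items()}
    name_of = {"T": "thermal", "S": "haline", "AT": "alkalinity", "CT": "dic"}
    y0m, y0f = config.modern_decade[0], config.future_decade[0]
    nd = config.modern_decade[1] - config.modern_decade[0] + 1
    for d in taylor.DRIVERS:
        x = yr_anoms[d]
        g = yr_gamma[d]
        inc = np.zeros((12, x.shape[-1]))
        for y in range(y0m, config.future_decade[1]):
            i = int(y - years[0])
            lo = max(0, y - y0f + 1)
            hi = min(nd - 1, y - y0m)
            if hi < lo:
                continue
            w = (hi - lo + 1) / nd
            gbar = 0.5 * (g[i] + g[i + 1])
            xbar = 0.5 * (x[i] + x[i + 1])
            inc = inc + w * (gbar * (x[i + 1] - x[i]) + xbar * (g[i + 1] - g[i]))
        inc_terms[name_of[d]] = inc_terms[name_of[d]] + inc @ dom_w
    result.future_terms_incremental = taylor.TermSeries(
        terms=inc_terms, layout="standard", actual_total=actual1,
        decade=config.future_decade,
    )

    # climate-CO2 separation on basin-mean gammas and anomalies
    sep = separation.separate_climate_co2(
        {d: gam0[d] @ dom_w for d in taylor.DRIVERS},
        {d: an0[d] @ dom_w for d in taylor.DRIVERS},
        {d: gam1[d] @ dom_w for d in taylor.DRIVERS},
        {d: an1[d] @ dom_w for d in taylor.DRIVERS},
    )
    result.separation = sep
    result.enhancement_extreme = separation.summer_enhancement(
        sep, config.summer_window, statistic="extreme"
    )
    result.enhancement_mean = separation.summer_enhancement(
        sep, config.summer_window, statistic="mean"
    )

    # CO2-system diagnostics at the basin modern mean state
    h_anom = _decadal_monthly_means(yearly_anoms(sol["H"]), years,
                                    config.modern_decade) @ dom_w
    result.h_pco2_correlation = float(np.corrcoef(h_anom, actual0)[0, 1])
    mstate = carbonate.SeawaterState(
        T=float(mod["T"].mean(axis=0) @ dom_w),
        S=float(mod["S"].mean(axis=0) @ dom_w),
        AT=float(mod["AT"].mean(axis=0) @ dom_w),
        CT=float(mod["CT"].mean(axis=0) @ dom_w),
    )
    result.temperature_sensitivity_ratio = carbonate.temperature_sensitivity_ratio(
        mstate
    )
    return result


def _ensemble_stats(values):
    vals = [v for v in values if v is not None and np.isfinite(v)]
    if not vals:
        return {"mean": None, "sd": None, "n": 0}
    return {"mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
            "n": len(vals)}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every ensemble member and aggregate mean +/- s.d. summaries."""
    grid, regions = build_masks(**config.grid_kwargs)
    members = []
    for seed in config.seeds:
        if config.input_path is not None:
            ds = xr.open_dataset(config.input_path, engine="scipy")
            truth = None
        else:
            params = synthetic.EmulatorParams(
                **{**asdict(config.params), "seed": int(seed)}
            )
            ds, truth = synthetic.generate_fields(
                params, config.scenario, grid, config.summer_window
            )
        members.append(
            analyze_dataset(ds, grid, regions, config, truth=truth, seed=int(seed))
        )
    summary = {
        "n_members": len(members),
        "crossover_ppm": _ensemble_stats(
            [m.crossover.co2_ppm if m.crossover else None for m in members]
        ),
        "shelf_crossover_ppm": _ensemble_stats(
            [m.shelf_crossover_ppm for m in members]
        ),
        "basin_crossover_ppm": _ensemble_stats(
            [m.basin_crossover_ppm for m in members]
        ),
        "enhancement_extreme_pct": _ensemble_stats(
            [m.enhancement_extreme for m in members]
        ),
        "enhancement_mean_pct": _ensemble_stats(
            [m.enhancement_mean for m in members]
        ),
        "h_pco2_correlation": _ensemble_stats(
            [m.h_pco2_correlation for m in members]
        ),
        "temperature_sensitivity_ratio": _ensemble_stats(
            [m.temperature_sensitivity_ratio for m in members]
        ),
    }
    if any(m.truth is not None for m in members):
        summary["truth_crossover_ppm"] = _ensemble_stats(
            [m.truth.crossover_ppm if m.truth else None for m in members]
        )
    return PipelineResult(members=members, summary=summary)
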