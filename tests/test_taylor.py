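"""Taylor decompositions: additivity, layouts, closure, incremental form."""

import numpy as np
import pytest

from pco2season.carbonate import sensitivity_arrays, solve_arrays
from pco2season.taylor import (
    DriverAnomalies,
    TermSeries,
    basic_gamma,
    freshwater_terms,
    incremental_future_decomposition,
    taylor_terms,
    thermal_nonthermal_split,
)

MONTHS = np.arange(1, 13, dtype=float)


def smooth_cell(t_amp=1.0, ct_amp=15.0, s_amp=0.1, at_amp=3.0,
                t0=1.0, s0=33.0, at0=2230.0, ct0=2100.0):
    """Monthly climatological means of a mildly seasonal polar cell."""
    phase = 2 * np.pi * (MONTHS - 8) / 12.0
    t = t0 + t_amp * np.cos(phase)
    ct = ct0 - ct_amp * np.cos(phase - 0.5)
    s = s0 - s_amp * np.sin(phase)
    at = at0 + at_amp * np.sin(phase + 0.3)
    return t, s, at, ct


def gamma_for(t, s, at, ct):
    monthly = sensitivity_arrays(t, s, at, ct)
    annual = sensitivity_arrays(t.mean(), s.mean(), at.mean(), ct.mean())
    return basic_gamma(monthly, annual)


def actual_prime(t, s, at, ct):
    p = solve_arrays(t, s, at, ct)["pCO2"]
    return p - p.mean()


class TestStandardLayout:
    def test_zero_anomalies_zero_terms(self):
        anoms = DriverAnomalies.from_monthly_means(
            np.full(12, 1.0), np.full(12, 33.0), np.full(12, 2230.0),
            np.full(12, 2100.0))
        ts = taylor_terms(anoms, {"T": 15.0, "S": 8.0, "AT": -2.0, "CT": 2.4})
        assert np.allclose(ts.reconstructed_total, 0.0)

    def test_only_thermal(self):
        t, s, at, ct = smooth_cell(ct_amp=0.0, s_amp=0.0, at_amp=0.0)
        anoms = DriverAnomalies.from_monthly_means(t, s, at, ct)
        ts = taylor_terms(anoms, {"T": 15.0, "S": 8.0, "AT": -2.0, "CT": 2.4})
        assert np.array_equal(ts.reconstructed_total, ts.terms["thermal"])

    def test_closure_against_direct_solves(self):
        t, s, at, ct = smooth_cell()
        anoms = DriverAnomalies.from_monthly_means(t, s, at, ct)
        ts = taylor_terms(anoms, gamma_for(t, s, at, ct),
                          actual_total=actual_prime(t, s, at, ct))
        amp = np.ptp(ts.actual_total)
        assert np.abs(ts.closure_error).max() < 0.05 * amp

    def test_closure_degrades_monotonically_with_amplitude(self):
        errs = []
        for scale in (0.5, 1.0, 2.0, 4.0):
            t, s, at, ct = smooth_cell(t_amp=1.0 * scale, ct_amp=15.0 * scale)
            anoms = DriverAnomalies.from_monthly_means(t, s, at, ct)
            ts = taylor_terms(anoms, gamma_for(t, s, at, ct),
                              actual_total=actual_prime(t, s, at, ct))
            errs.append(np.abs(ts.closure_error).max())
        assert np.all(np.diff(errs) > 0)


class TestFreshwaterLayout:
    def test_constant_salinity_reduces_to_standard(self):
        t, s, at, ct = smooth_cell(s_amp=0.0)
        anoms = DriverAnomalies.from_monthly_means(t, s, at, ct)
        g = gamma_for(t, s, at, ct)
        fw = freshwater_terms(anoms, g)
        std = taylor_terms(anoms, g)
        assert np.allclose(fw.terms["fw_alkalinity"], 0.0, atol=1e-12)
        assert np.allclose(fw.terms["fw_dic"], 0.0, atol=1e-12)
        assert np.allclose(fw.terms["bio_sAT"], std.terms["alkalinity"], atol=1e-9)
        assert np.allclose(fw.terms["bio_sCT"], std.terms["dic"], atol=1e-9)

    def test_pure_dilution_is_all_freshwater(self):
        # melt-season freshening: S dips and AT, CT dilute proportionally
        s = 33.0 - 0.5 * np.exp(-0.5 * ((MONTHS - 6) / 1.5) ** 2)
        factor = s / 33.0
        t = np.full(12, 1.0)
        at, ct = 2230.0 * factor, 2100.0 * factor
        anoms = DriverAnomalies.from_monthly_means(t, s, at, ct)
        g = gamma_for(t, s, at, ct)
        fw = freshwater_terms(anoms, g)
        bio = np.abs(fw.terms["bio_sAT"]) + np.abs(fw.terms["bio_sCT"])
        fw_part = (np.abs(fw.terms["fw_alkalinity"]) + np.abs(fw.terms["fw_dic"]))
        assert bio.max() < 0.02 * fw_part.max()

    def test_layouts_share_identical_totals(self):
        t, s, at, ct = smooth_cell(s_amp=0.4)
        anoms = DriverAnomalies.from_monthly_means(t, s, at, ct)
        g = gamma_for(t, s, at, ct)
        total_std = taylor_terms(anoms, g).reconstructed_total
        total_fw = freshwater_terms(anoms, g).reconstructed_total
        assert np.abs(total_std - total_fw).max() < 1e-6

    def test_zero_salinity_month_fails(self):
        anoms = DriverAnomalies(
            Tprime=np.zeros(12), Sprime=np.full(12, -33.0), ATprime=np.zeros(12),
            CTprime=np.zeros(12), S0=33.0, sATprime=np.zeros(12),
            sCTprime=np.zeros(12), sAT_mean=2230.0, sCT_mean=2100.0)
        with pytest.raises(ValueError):
            freshwater_terms(anoms, {"T": 1, "S": 1, "AT": 1, "CT": 1})


class TestIncremental:
    def setup_series(self, nyears=30, trend_per_year=0.0, curvature=0.0):
        """Per-year anomalies with optional growth of the seasonal amplitude."""
        years = np.arange(2000, 2000 + nyears)
        base = np.cos(2 * np.pi * (MONTHS - 8) / 12.0)
        scale = 1.0 + trend_per_year * np.arange(nyears) + curvature * (
            np.arange(nyears) / nyears) ** 3
        anoms = scale[:, None] * base[None, :]
        anoms = anoms - anoms.mean(axis=1, keepdims=True)
        return years, {d: anoms for d in ("T", "S", "AT", "CT")}

    def test_stationary_drivers_return_modern_terms(self):
        years, anoms = self.setup_series(trend_per_year=0.0)
        gamma = {d: np.full((30, 12), 2.0) for d in ("T", "S", "AT", "CT")}
        modern = TermSeries(
            terms={"thermal": np.ones(12), "haline": np.zeros(12),
                   "alkalinity": np.zeros(12), "dic": np.zeros(12)},
            layout="standard")
        fut = incremental_future_decomposition(
            anoms, gamma, years, modern, (2000, 2009), (2020, 2029))
        for k in modern.terms:
            assert np.allclose(fut.terms[k], modern.terms[k])

    def test_telescopes_to_basic_for_linear_drivers_constant_gamma(self):
        years, anoms = self.setup_series(trend_per_year=0.05)
        g = {"T": 15.0, "S": 8.0, "AT": -2.0, "CT": 2.4}
        gamma = {d: np.full((30, 12), g[d]) for d in g}
        modern_mean = {d: anoms[d][0:10].mean(axis=0) for d in g}
        future_mean = {d: anoms[d][20:30].mean(axis=0) for d in g}
        modern = TermSeries(
            terms={"thermal": g["T"] * modern_mean["T"],
                   "haline": g["S"] * modern_mean["S"],
                   "alkalinity": g["AT"] * modern_mean["AT"],
                   "dic": g["CT"] * modern_mean["CT"]},
            layout="standard")
        fut = incremental_future_decomposition(
            anoms, gamma, years, modern, (2000, 2009), (2020, 2029))
        assert np.allclose(fut.terms["thermal"], g["T"] * future_mean["T"],
                           atol=1e-10)
        assert np.allclose(fut.terms["dic"], g["CT"] * future_mean["CT"],
                           atol=1e-10)

    def test_gap_in_years_fails(self):
        years, anoms = self.setup_series()
        years = years.copy()
        years[5:] += 1
        gamma = {d: np.full((30, 12), 2.0) for d in ("T", "S", "AT", "CT")}
        modern = TermSeries(terms={"thermal": np.zeros(12), "haline": np.zeros(12),
                                   "alkalinity": np.zeros(12), "dic": np.zeros(12)},
                            layout="standard")
        with pytest.raises(ValueError):
            incremental_future_decomposition(
                anoms, gamma, years, modern, (2000, 2009), (2021, 2030))

    def test_beats_basic_on_strongly_trending_scenario(self, member):
        """On the default strong-forcing century the incremental form must
        close better than the basic approach for the future decade."""
        basic = np.abs(member.future_terms_basic.closure_error).max()
        incremental = np.abs(member.future_terms_incremental.closure_error).max()
        assert incremental < basic


class TestSplit:
    def test_only_thermal_leaves_zero_nonthermal(self):
        ts = TermSeries(terms={"thermal": np.ones(12), "haline": np.zeros(12),
                               "alkalinity": np.zeros(12), "dic": np.zeros(12)},
                        layout="standard")
        thermal, nonthermal = thermal_nonthermal_split(ts)
        assert np.allclose(nonthermal, 0.0)

    def test_split_is_exact_partition(self, rng):
        terms = {k: rng.normal(0, 5, 12) for k in
                 ("thermal", "haline", "alkalinity", "dic")}
        ts = TermSeries(terms=terms, layout="standard")
        thermal, nonthermal = thermal_nonthermal_split(ts)
        assert np.allclose(thermal + nonthermal, ts.reconstructed_total,
                           rtol=0, atol=1e-12)

    def test_residual_basis_differs_by_closure_error(self, rng):
        terms = {k: rng.normal(0, 5, 12) for k in
                 ("thermal", "haline", "alkalinity", "dic")}
        actual = rng.normal(0, 5, 12)
        ts = TermSeries(terms=terms, layout="standard", actual_total=actual)
        _, nt_rec = thermal_nonthermal_split(ts, basis="reconstructed")
        _, nt_act = thermal_nonthermal_split(ts, basis="actual")
        assert np.allclose(nt_rec - nt_act, ts.closure_error)
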