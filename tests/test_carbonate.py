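"""Carbonate-system solver: identities, oracle agreement, sensitivities."""

import numpy as np
import pytest

from pco2season.carbonate import (
    CarbonateError,
    SeawaterState,
    compute_sensitivities,
    solve_arrays,
    solve_carbonate,
    temperature_sensitivity_ratio,
)
from pco2season.constants import DEFAULT_CONSTANTS

REF = dict(AT=2130.0, CT=2000.0)  # reference polar-surface composition


def alkalinity_residual_oracle(ph, state: SeawaterState) -> float:
    """Test-local total-alkalinity balance, written independently.

    Recomputes speciation from the constants registry in plain scalar code
    and returns TA(pH) - AT (mol/kg).
    """
    c = DEFAULT_CONSTANTS
    t, s = state.T, state.S
    h = 10.0**-ph
    k1, k2 = float(c.k1(t, s)), float(c.k2(t, s))
    kb, kw = float(c.kb(t, s)), float(c.kw(t, s))
    ks, bt, st = float(c.ks(t, s)), float(c.bt(s)), float(c.st(s))
    kp1, kp2, kp3 = (float(f(t, s)) for f in (c.kp1, c.kp2, c.kp3))
    ksi = float(c.ksi(t, s))
    ct, at = state.CT * 1e-6, state.AT * 1e-6
    pt, sit = state.PT * 1e-6, state.SiT * 1e-6
    den = h**2 + k1 * h + k1 * k2
    hco3 = ct * k1 * h / den
    co3 = ct * k1 * k2 / den
    den3 = h**3 + kp1 * h**2 + kp1 * kp2 * h + kp1 * kp2 * kp3
    palk = pt * (kp1 * kp2 * h + 2 * kp1 * kp2 * kp3 - h**3) / den3
    ta = (
        hco3
        + 2 * co3
        + bt * kb / (kb + h)
        + kw / h
        - h / (1.0 + st / ks)
        + sit * ksi / (ksi + h)
        + palk
    )
    return ta - at


def bisect_ph(state: SeawaterState, tol: float = 1e-11) -> float:
    """Brute-force bisection of the alkalinity balance over pH in [2, 12]."""
    lo, hi = 2.0, 12.0
    flo = alkalinity_residual_oracle(lo, state)
    fhi = alkalinity_residual_oracle(hi, state)
    assert flo * fhi < 0, "oracle bracket failed"
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = alkalinity_residual_oracle(mid, state)
        if fm * flo <= 0:
            hi = mid
        else:
            lo, flo = mid, fm
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def random_ocean_states(rng, n):
    return [
        SeawaterState(
            T=float(rng.uniform(-1.8, 25.0)),
            S=float(rng.uniform(30.0, 37.0)),
            AT=float(rng.uniform(2100.0, 2450.0)),
            CT=float(rng.uniform(1850.0, 2250.0)),
            PT=float(rng.uniform(0.0, 2.0)),
            SiT=float(rng.uniform(0.0, 60.0)),
        )
        for _ in range(n)
    ]


class TestSolver:
    def test_reference_composition_identities(self):
        sol = solve_carbonate(SeawaterState(T=2.0, S=33.0, **REF))
        # Henry/K1 identity: pCO2 = H * HCO3 / (Cf K0 K1)
        recon = sol.H * (sol.HCO3 * 1e-6) / (sol.Cf * sol.K0 * sol.K1) * 1e6
        assert abs(recon - sol.pCO2) / sol.pCO2 < 1e-8
        # carbon conservation
        total = sol.CO2star + sol.HCO3 + sol.CO3
        assert abs(total - REF["CT"]) / REF["CT"] < 1e-6
        assert 0.99 < sol.Cf <= 1.0
        assert 7.5 < sol.pH < 8.5

    def test_zero_carbon_means_zero_pco2(self):
        sol = solve_carbonate(SeawaterState(T=2.0, S=33.0, AT=2130.0, CT=0.0))
        assert sol.pCO2 == 0.0
        assert sol.CO2star == 0.0

    def test_agrees_with_bisection_oracle(self, rng):
        for state in random_ocean_states(rng, 100):
            sol = solve_carbonate(state)
            assert abs(sol.pH - bisect_ph(state)) < 1e-8

    def test_monotone_in_ct_and_at(self):
        cts = np.linspace(1900, 2100, 21)
        p_ct = solve_arrays(2.0, 33.0, 2130.0, cts)["pCO2"]
        assert np.all(np.diff(p_ct) > 0)
        ats = np.linspace(2100, 2400, 21)
        p_at = solve_arrays(2.0, 33.0, ats, 2000.0)["pCO2"]
        assert np.all(np.diff(p_at) < 0)

    def test_h_tracks_pco2_linearly_at_fixed_t(self):
        cts = np.linspace(1900, 2100, 41)
        out = solve_arrays(2.0, 33.0, 2130.0, cts)
        r = np.corrcoef(out["H"], out["pCO2"])[0, 1]
        assert r > 0.999

    def test_unphysical_combination_fails_loudly(self):
        # enormous alkalinity with no carbon or borate buffering at pH <= 12
        with pytest.raises(CarbonateError):
            solve_arrays(2.0, 0.0, 50000.0, 0.0)

    def test_state_validation(self):
        with pytest.raises(ValueError):
            SeawaterState(T=50.0, S=33.0, **REF)
        with pytest.raises(ValueError):
            SeawaterState(T=2.0, S=33.0, AT=-1.0, CT=2000.0)


class TestSensitivities:
    def test_sign_pattern(self, rng):
        for state in random_ocean_states(rng, 5):
            sv = compute_sensitivities(state)
            assert sv.dpco2_dT > 0
            assert sv.dpco2_dCT > 0
            assert sv.dpco2_dAT < 0

    def test_step_halving_converged(self):
        state = SeawaterState(T=2.0, S=33.0, **REF)
        full = compute_sensitivities(state)
        half = compute_sensitivities(
            state, steps={"T": 5e-4, "S": 5e-4, "AT": 0.05, "CT": 0.05}
        )
        for a, b in zip(full.as_array(), half.as_array()):
            assert abs(a - b) / abs(b) < 1e-4

    def test_matches_independent_secant(self):
        state = SeawaterState(T=2.0, S=33.0, **REF)
        sv = compute_sensitivities(state)
        h = 0.01  # coarse independent secant step
        p_hi = solve_carbonate(state.replace(T=state.T + h)).pCO2
        p_lo = solve_carbonate(state.replace(T=state.T - h)).pCO2
        secant = (p_hi - p_lo) / (2 * h)
        assert abs(sv.dpco2_dT - secant) / secant < 1e-3
        # normalized thermal sensitivity in the canonical ocean band
        p0 = solve_carbonate(state).pCO2
        assert 0.03 < sv.dpco2_dT / p0 < 0.06


class TestTemperatureSensitivityRatio:
    def test_about_seven_for_near_freezing_polar_water(self):
        """Closed-system pCO2/[CO2*] thermal response ratio ~7 near freezing."""
        ratios = [
            temperature_sensitivity_ratio(SeawaterState(T=t, S=s, **REF))
            for t in (-1.8, -1.0, 0.0)
            for s in (32.0, 34.0)
        ]
        assert abs(np.mean(ratios) - 7.0) < 0.5
        assert all(6.0 < r < 8.0 for r in ratios)

    def test_henrys_law_identity(self):
        """d ln pCO2/dT - d ln CO2*/dT = -d ln(K0 Cf)/dT at fixed AT, CT."""
        state = SeawaterState(T=0.0, S=33.0, **REF)
        h = 1e-3
        lo = solve_carbonate(state.replace(T=state.T - h))
        hi = solve_carbonate(state.replace(T=state.T + h))
        lhs = (np.log(hi.pCO2) - np.log(lo.pCO2)) / (2 * h) - (
            np.log(hi.CO2star) - np.log(lo.CO2star)
        ) / (2 * h)
        rhs = -(np.log(hi.K0 * hi.Cf) - np.log(lo.K0 * lo.Cf)) / (2 * h)
        assert abs(lhs - rhs) < 1e-6

    def test_equals_ratio_of_independent_secants(self):
        state = SeawaterState(T=0.0, S=33.0, **REF)
        r = temperature_sensitivity_ratio(state)
        h = 0.005
        lo = solve_carbonate(state.replace(T=state.T - h))
        hi = solve_carbonate(state.replace(T=state.T + h))
        r_sec = (np.log(hi.pCO2) - np.log(lo.pCO2)) / (
            np.log(hi.CO2star) - np.log(lo.CO2star)
        )
        assert abs(r - r_sec) / r_sec < 1e-3
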