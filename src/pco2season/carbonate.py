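"""Seawater CO2-system equilibrium solver and pCO2 sensitivities.

The solver takes the two conservative carbon-system variables (total
alkalinity A_T and total dissolved inorganic carbon C_T) together with
temperature, salinity and the minor nutrient totals, and finds the total-scale
hydrogen-ion concentration that closes the alkalinity balance

    A_T = [HCO3-] + 2[CO3--] + [B(OH)4-] + [OH-] - [H+]_free
          + phosphate alkalinity + [SiO(OH)3-]

by a safeguarded Newton iteration on pH with a bisection fallback inside the
bracket pH in [2, 12].  Minor acid-base pairs (NH3, H2S, HF/HSO4 beyond the
pH-scale conversion) are omitted; they are negligible at open-ocean
concentrations.  From the root, the full speciation and pCO2 follow from
Henry's law, pCO2 = [CO2*] / (K0 Cf), with the fugacity coefficient Cf
evaluated at 1 atm (surface waters only).

Everything is vectorized: the array entry points (`solve_arrays`,
`sensitivity_arrays`) drive whole gridded fields through the same Newton
iteration at once, which is what makes century-scale synthetic pipelines
affordable.  The scalar dataclass API wraps them for single-state work.

Units: µmol kg-1 at the public surface, mol kg-1 internally; pCO2 in µatm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ConstantsSet, DEFAULT_CONSTANTS

__all__ = [
    "SeawaterState",
    "CarbonateSolution",
    "SensitivityVector",
    "CarbonateError",
    "solve_carbonate",
    "solve_arrays",
    "compute_sensitivities",
    "sensitivity_arrays",
    "temperature_sensitivity_ratio",
]

# central finite-difference steps per driver (T degC, S, AT/CT µmol kg-1)
DEFAULT_STEPS = {"T": 1e-3, "S": 1e-3, "AT": 0.1, "CT": 0.1}

T_RANGE = (-2.0, 40.0)
S_RANGE = (0.0, 45.0)

_PH_LO, _PH_HI = 2.0, 12.0
_MAX_ITER = 100
_H_RTOL = 1e-12


class CarbonateError(RuntimeError):
    """Raised when the alkalinity balance cannot be solved for a state."""


@dataclass(frozen=True)
class SeawaterState:
    """One surface-water state: the four Taylor drivers plus nutrients.

    T in degC, S practical salinity, A_T/C_T/P_T/Si_T in µmol kg-1.
    """

    T: float
    S: float
    AT: float
    CT: float
    PT: float = 0.0
    SiT: float = 0.0

    def __post_init__(self) -> None:
        if not (T_RANGE[0] <= self.T <= T_RANGE[1]):
            raise ValueError(f"temperature {self.T} degC outside {T_RANGE}")
        if not (S_RANGE[0] <= self.S <= S_RANGE[1]):
            raise ValueError(f"salinity {self.S} outside {S_RANGE}")
        for name in ("AT", "CT", "PT", "SiT"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def replace(self, **kwargs) -> "SeawaterState":
        data = {k: getattr(self, k) for k in ("T", "S", "AT", "CT", "PT", "SiT")}
        data.update(kwargs)
        return SeawaterState(**data)


@dataclass(frozen=True)
class CarbonateSolution:
    """Full equilibrium speciation for one state (concentrations µmol kg-1)."""

    pH: float
    H: float  # mol kg-1, total scale
    pCO2: float  # µatm
    CO2star: float
    HCO3: float
    CO3: float
    K0: float  # mol kg-1 atm-1
    K1: float
    K2: float
    Cf: float
    constants: str = DEFAULT_CONSTANTS.name


@dataclass(frozen=True)
class SensitivityVector:
    """Partial derivatives of pCO2 with respect to each driver."""

    dpco2_dT: float  # µatm / degC
    dpco2_dS: float  # µatm / salinity unit
    dpco2_dAT: float  # µatm / (µmol kg-1)
    dpco2_dCT: float  # µatm / (µmol kg-1)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.dpco2_dT, self.dpco2_dS, self.dpco2_dAT, self.dpco2_dCT]
        )


def _alkalinity_residual(h, ct, at, bt, pt, sit, k):
    """Total alkalinity computed from [H+] minus the prescribed A_T.

    All concentrations mol kg-1; h on the total scale.  Returns the residual
    and its analytic derivative with respect to h.
    """
    k1, k2, kb, kw, ks, kp1, kp2, kp3, ksi, st = k
    den = h * h + k1 * h + k1 * k2
    hco3 = ct * k1 * h / den
    co3 = ct * k1 * k2 / den
    boh4 = bt * kb / (kb + h)
    oh = kw / h
    free_factor = 1.0 / (1.0 + st / ks)
    h_free = h * free_factor
    sialk = sit * ksi / (ksi + h)
    # phosphate: charge-weighted sum relative to H3PO4 reference
    den3 = h**3 + kp1 * h**2 + kp1 * kp2 * h + kp1 * kp2 * kp3
    pnum = kp1 * kp2 * h + 2.0 * kp1 * kp2 * kp3 - h**3
    palk = pt * pnum / den3
    resid = hco3 + 2.0 * co3 + boh4 + oh - h_free + sialk + palk - at

    dden = 2.0 * h + k1
    dhco3 = ct * k1 * (den - h * dden) / den**2
    dco3 = -ct * k1 * k2 * dden / den**2
    dboh4 = -bt * kb / (kb + h) ** 2
    doh = -kw / h**2
    dsialk = -sit * ksi / (ksi + h) ** 2
    dden3 = 3.0 * h**2 + 2.0 * kp1 * h + kp1 * kp2
    dpnum = kp1 * kp2 - 3.0 * h**2
    dpalk = pt * (dpnum * den3 - pnum * dden3) / den3**2
    dresid = dhco3 + 2.0 * dco3 + dboh4 + doh - free_factor + dsialk + dpalk
    return resid, dresid


def solve_arrays(
    t_c,
    s,
    at,
    ct,
    pt=0.0,
    sit=0.0,
    constants: ConstantsSet = DEFAULT_CONSTANTS,
):
    """Solve the CO2 system for broadcastable arrays of driver fields.

    A_T, C_T, P_T, Si_T in µmol kg-1.  Returns a dict of arrays: pH, H
    (mol kg-1), pCO2 (µatm), CO2star/HCO3/CO3 (µmol kg-1), K0, K1, K2, Cf.

    Raises `CarbonateError` if any element fails to bracket a root in
    pH [2, 12] or the Newton/bisection iteration does not converge.
    """
    t_c, s, at_u, ct_u, pt_u, sit_u = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (t_c, s, at, ct, pt, sit))
    )
    shape = t_c.shape
    at_m = at_u * 1e-6
    ct_m = ct_u * 1e-6
    pt_m = pt_u * 1e-6
    sit_m = sit_u * 1e-6

    k1 = constants.k1(t_c, s)
    k2 = constants.k2(t_c, s)
    k = (
        k1,
        k2,
        constants.kb(t_c, s),
        constants.kw(t_c, s),
        constants.ks(t_c, s),
        constants.kp1(t_c, s),
        constants.kp2(t_c, s),
        constants.kp3(t_c, s),
        constants.ksi(t_c, s),
        constants.st(s),
    )
    bt = constants.bt(s)

    h_lo = np.full(shape, 10.0**-_PH_HI)  # alkaline end: residual > 0 expected
    h_hi = np.full(shape, 10.0**-_PH_LO)  # acid end: residual < 0 expected
    f_lo, _ = _alkalinity_residual(h_lo, ct_m, at_m, bt, pt_m, sit_m, k)
    f_hi, _ = _alkalinity_residual(h_hi, ct_m, at_m, bt, pt_m, sit_m, k)
    bad = (f_lo < 0) | (f_hi > 0)
    if np.any(bad):
        idx = np.argwhere(bad)[0]
        raise CarbonateError(
            "no physical root in pH [2, 12] for state "
            f"T={t_c[tuple(idx)]:.3f} S={s[tuple(idx)]:.3f} "
            f"AT={at_u[tuple(idx)]:.1f} CT={ct_u[tuple(idx)]:.1f}"
        )

    h = np.full(shape, 1e-8)  # pH 8 initial guess
    converged = np.zeros(shape, dtype=bool)
    for _ in range(_MAX_ITER):
        f, df = _alkalinity_residual(h, ct_m, at_m, bt, pt_m, sit_m, k)
        # maintain the bracket (residual decreases with h)
        h_lo = np.where(f > 0, h, h_lo)
        h_hi = np.where(f < 0, h, h_hi)
        # Newton step in ln h keeps h positive
        dlnh = -f / (df * h)
        dlnh = np.clip(dlnh, -1.0, 1.0)
        h_new = h * np.exp(dlnh)
        outside = (h_new <= h_lo) | (h_new >= h_hi)
        h_new = np.where(outside, np.sqrt(h_lo * h_hi), h_new)
        step = np.abs(h_new - h) / h
        converged = step < _H_RTOL
        h = h_new
        if converged.all():
            break
    if not converged.all():
        idx = np.argwhere(~converged)[0]
        raise CarbonateError(
            "carbonate solver did not converge for state "
            f"T={t_c[tuple(idx)]:.3f} S={s[tuple(idx)]:.3f} "
            f"AT={at_u[tuple(idx)]:.1f} CT={ct_u[tuple(idx)]:.1f}"
        )

    den = h * h + k1 * h + k1 * k2
    co2star = ct_m * h * h / den
    hco3 = ct_m * k1 * h / den
    co3 = ct_m * k1 * k2 / den
    k0 = constants.k0(t_c, s)
    cf = constants.cf(t_c)
    pco2 = co2star / (k0 * cf) * 1e6  # atm -> µatm
    with np.errstate(divide="ignore"):
        ph = -np.log10(h)
    return {
        "pH": ph,
        "H": h,
        "pCO2": pco2,
        "CO2star": co2star * 1e6,
        "HCO3": hco3 * 1e6,
        "CO3": co3 * 1e6,
        "K0": k0,
        "K1": k1,
        "K2": k2,
        "Cf": cf,
    }


def solve_carbonate(
    state: SeawaterState, constants: ConstantsSet = DEFAULT_CONSTANTS
) -> CarbonateSolution:
    """Solve the CO2 system for a single state."""
    out = solve_arrays(
        state.T, state.S, state.AT, state.CT, state.PT, state.SiT, constants
    )
    return CarbonateSolution(
        pH=float(out["pH"]),
        H=float(out["H"]),
        pCO2=float(out["pCO2"]),
        CO2star=float(out["CO2star"]),
        HCO3=float(out["HCO3"]),
        CO3=float(out["CO3"]),
        K0=float(out["K0"]),
        K1=float(out["K1"]),
        K2=float(out["K2"]),
        Cf=float(out["Cf"]),
        constants=constants.name,
    )


def _perturbed_pair(state: SeawaterState, driver: str, step: float):
    """States at +/- step in one driver, shrinking the step once if needed."""
    for attempt_step in (step, step / 10.0):
        try:
            lo = state.replace(**{driver: getattr(state, driver) - attempt_step})
            hi = state.replace(**{driver: getattr(state, driver) + attempt_step})
            return lo, hi, attempt_step
        except ValueError:
            continue
    raise CarbonateError(
        f"cannot perturb driver {driver} of state {state} within valid ranges"
    )


def compute_sensitivities(
    state: SeawaterState,
    steps: dict | None = None,
    constants: ConstantsSet = DEFAULT_CONSTANTS,
) -> SensitivityVector:
    """Central-difference sensitivities of pCO2 to (T, S, A_T, C_T).

    Each driver is perturbed with the others held fixed.  If a perturbed
    state leaves the valid range the step is shrunk once (x0.1) before
    failing.
    """
    steps = {**DEFAULT_STEPS, **(steps or {})}
    vals = {}
    for driver in ("T", "S", "AT", "CT"):
        lo, hi, h = _perturbed_pair(state, driver, steps[driver])
        p_lo = solve_carbonate(lo, constants).pCO2
        p_hi = solve_carbonate(hi, constants).pCO2
        vals[driver] = (p_hi - p_lo) / (2.0 * h)
    return SensitivityVector(
        dpco2_dT=vals["T"],
        dpco2_dS=vals["S"],
        dpco2_dAT=vals["AT"],
        dpco2_dCT=vals["CT"],
    )


def sensitivity_arrays(
    t_c,
    s,
    at,
    ct,
    pt=0.0,
    sit=0.0,
    steps: dict | None = None,
    constants: ConstantsSet = DEFAULT_CONSTANTS,
):
    """Vectorized central-difference pCO2 sensitivities for gridded fields.

    Returns a dict with keys "T", "S", "AT", "CT" (µatm per driver unit).
    """
    steps = {**DEFAULT_STEPS, **(steps or {})}
    base = dict(t_c=np.asarray(t_c, float), s=np.asarray(s, float),
                at=np.asarray(at, float), ct=np.asarray(ct, float),
                pt=pt, sit=sit)
    keymap = {"T": "t_c", "S": "s", "AT": "at", "CT": "ct"}
    out = {}
    for driver, key in keymap.items():
        h = steps[driver]
        lo = dict(base)
        hi = dict(base)
        lo[key] = base[key] - h
        hi[key] = base[key] + h
        p_lo = solve_arrays(lo["t_c"], lo["s"], lo["at"], lo["ct"],
                            lo["pt"], lo["sit"], constants)["pCO2"]
        p_hi = solve_arrays(hi["t_c"], hi["s"], hi["at"], hi["ct"],
                            hi["pt"], hi["sit"], constants)["pCO2"]
        out[driver] = (p_hi - p_lo) / (2.0 * h)
    return out


def temperature_sensitivity_ratio(
    state: SeawaterState,
    step: float | None = None,
    constants: ConstantsSet = DEFAULT_CONSTANTS,
) -> float:
    """Closed-system ratio (d ln pCO2/dT) / (d ln [CO2*]/dT).

    A_T and C_T are held fixed while T is perturbed, so the carbon content
    cannot adjust by air-sea exchange: the ratio isolates how much more
    strongly pCO2 responds to warming than the dissolved CO2 it tracks
    through the solubility K0.  Raises if the [CO2*] response is below step
    noise (ratio undefined).
    """
    h = step if step is not None else DEFAULT_STEPS["T"]
    lo, hi, h = _perturbed_pair(state, "T", h)
    sol_lo = solve_carbonate(lo, constants)
    sol_hi = solve_carbonate(hi, constants)
    dln_pco2 = (np.log(sol_hi.pCO2) - np.log(sol_lo.pCO2)) / (2.0 * h)
    dln_co2star = (np.log(sol_hi.CO2star) - np.log(sol_lo.CO2star)) / (2.0 * h)
    if abs(dln_co2star) < 1e3 * np.finfo(float).eps / h:
        raise CarbonateError(
            f"d ln [CO2*]/dT is zero within step noise for state {state}; "
            "temperature-sensitivity ratio undefined"
        )
    return float(dln_pco2 / dln_co2star)
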