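"""Equilibrium constants for the seawater CO2 system.

All constants are evaluated on the total hydrogen-ion scale at 1 atm total
pressure (surface waters only) and in mol kg-sw units.  The default set
follows the community "best practices" choices used by the major CO2-system
packages:

* K0   — CO2 solubility, Weiss (1974)
* K1K2 — carbonic acid, Lueker, Dickson & Keeling (2000), total scale
* KB   — boric acid, Dickson (1990b)
* KW   — water, Millero (1995) as given in the DOE/Dickson handbook
* KS   — bisulfate, Dickson (1990a), free scale (used for scale conversion)
* KF   — hydrogen fluoride, Perez & Fraga (1987), total scale
* KP1-3, KSi — phosphoric and silicic acids, Millero (1995)
* Total borate — Uppstrom (1974); sulfate — Morris & Riley (1966);
  fluoride — Riley (1965); all proportional to salinity.

Functions are vectorized over numpy arrays of temperature (deg C) and
practical salinity.  A named registry keeps the set swappable and lets every
downstream output record which constants produced it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

# gas constant in cm3 atm mol-1 K-1 (for the fugacity virial correction)
R_GAS_CM3 = 82.05736


def _tk(t_c):
    return np.asarray(t_c, dtype=float) + 273.15


def k0_weiss74(t_c, s):
    """CO2 solubility K0 (mol kg-1 atm-1), Weiss (1974)."""
    tk = _tk(t_c)
    tk100 = tk / 100.0
    s = np.asarray(s, dtype=float)
    lnk0 = (
        -60.2409
        + 93.4517 / tk100
        + 23.3585 * np.log(tk100)
        + s * (0.023517 - 0.023656 * tk100 + 0.0047036 * tk100**2)
    )
    return np.exp(lnk0)


def k1_lueker00(t_c, s):
    """First carbonic-acid dissociation constant, total scale (mol kg-1)."""
    tk = _tk(t_c)
    s = np.asarray(s, dtype=float)
    pk1 = (
        3633.86 / tk
        - 61.2172
        + 9.6777 * np.log(tk)
        - 0.011555 * s
        + 0.0001152 * s**2
    )
    return 10.0 ** (-pk1)


def k2_lueker00(t_c, s):
    """Second carbonic-acid dissociation constant, total scale (mol kg-1)."""
    tk = _tk(t_c)
    s = np.asarray(s, dtype=float)
    pk2 = (
        471.78 / tk
        + 25.929
        - 3.16967 * np.log(tk)
        - 0.01781 * s
        + 0.0001122 * s**2
    )
    return 10.0 ** (-pk2)


def kb_dickson90(t_c, s):
    """Boric-acid dissociation constant, total scale (mol kg-1)."""
    tk = _tk(t_c)
    s = np.asarray(s, dtype=float)
    sq = np.sqrt(s)
    lnkb = (
        (-8966.90 - 2890.53 * sq - 77.942 * s + 1.728 * s * sq - 0.0996 * s**2) / tk
        + 148.0248
        + 137.1942 * sq
        + 1.62142 * s
        + (-24.4344 - 25.085 * sq - 0.2474 * s) * np.log(tk)
        + 0.053105 * sq * tk
    )
    return np.exp(lnkb)


def kw_millero95(t_c, s):
    """Ion product of water, total scale (mol2 kg-2), DOE handbook form."""
    tk = _tk(t_c)
    s = np.asarray(s, dtype=float)
    sq = np.sqrt(s)
    lnkw = (
        148.9652
        - 13847.26 / tk
        - 23.6521 * np.log(tk)
        + (118.67 / tk - 5.977 + 1.0495 * np.log(tk)) * sq
        - 0.01615 * s
    )
    return np.exp(lnkw)


def ks_dickson90(t_c, s):
    """Bisulfate dissociation constant, FREE scale (mol kg-1)."""
    tk = _tk(t_c)
    s = np.asarray(s, dtype=float)
    # ionic strength of seawater
    ist = 19.924 * s / (1000.0 - 1.005 * s)
    sq = np.sqrt(ist)
    lnks = (
        -4276.1 / tk
        + 141.328
        - 23.093 * np.log(tk)
        + (-13856.0 / tk + 324.57 - 47.986 * np.log(tk)) * sq
        + (35474.0 / tk - 771.54 + 114.723 * np.log(tk)) * ist
        - 2698.0 / tk * ist * sq
        + 1776.0 / tk * ist**2
    )
    # convert mol/kg-H2O -> mol/kg-sw
    return np.exp(lnks) * (1.0 - 0.001005 * s)


def kf_perezfraga87(t_c, s):
    """HF dissociation constant, total scale (mol kg-1)."""
    tk = _tk(t_c)
    s = np.asarray(s, dtype=float)
    lnkf = 874.0 / tk - 9.68 + 0.111 * np.sqrt(s)
    return np.exp(lnkf)


def kp1_millero95(t_c, s):
    tk = _tk(t_c)
    s = np.asarray(s, dtype=float)
    sq = np.sqrt(s)
    lnkp1 = (
        -4576.752 / tk
        + 115.525
        - 18.453 * np.log(tk)
        + (-106.736 / tk + 0.69171) * sq
        + (-0.65643 / tk - 0.01844) * s
    )
    return np.exp(lnkp1)


def kp2_millero95(t_c, s):
    tk = _tk(t_c)
    s = np.asarray(s, dtype=float)
    sq = np.sqrt(s)
    lnkp2 = (
        -8814.715 / tk
        + 172.0883
        - 27.927 * np.log(tk)
        + (-160.340 / tk + 1.3566) * sq
        + (0.37335 / tk - 0.05778) * s
    )
    return np.exp(lnkp2)


def kp3_millero95(t_c, s):
    tk = _tk(t_c)
    s = np.asarray(s, dtype=float)
    sq = np.sqrt(s)
    lnkp3 = (
        -3070.75 / tk
        - 18.141
        + (17.27039 / tk + 2.81197) * sq
        + (-44.99486 / tk - 0.09984) * s
    )
    return np.exp(lnkp3)


def ksi_millero95(t_c, s):
    tk = _tk(t_c)
    s = np.asarray(s, dtype=float)
    ist = 19.924 * s / (1000.0 - 1.005 * s)
    sq = np.sqrt(ist)
    lnksi = (
        -8904.2 / tk
        + 117.385
        - 19.334 * np.log(tk)
        + (-458.79 / tk + 3.5913) * sq
        + (188.74 / tk - 1.5998) * ist
        + (-12.1652 / tk + 0.07871) * ist**2
    )
    return np.exp(lnksi) * (1.0 - 0.001005 * s)


def total_borate(s):
    """Total boron (mol kg-1), Uppstrom (1974)."""
    return 0.0004157 * np.asarray(s, dtype=float) / 35.0


def total_sulfate(s):
    """Total sulfate (mol kg-1), Morris & Riley (1966)."""
    return 0.02824 * np.asarray(s, dtype=float) / 35.0


def total_fluoride(s):
    """Total fluoride (mol kg-1), Riley (1965)."""
    return 7.0e-5 * np.asarray(s, dtype=float) / 35.0


def fugacity_coefficient(t_c, p_atm: float = 1.0):
    """Fugacity coefficient Cf of CO2 at total pressure p_atm, Weiss (1974).

    Uses the virial coefficients of pure CO2 (B) and the CO2-air cross term
    (delta); the mole-fraction factor is taken as 1 (trace CO2).  Near unity
    at surface conditions (~0.996 at 0 degC).
    """
    tk = _tk(t_c)
    b = -1636.75 + 12.0408 * tk - 0.0327957 * tk**2 + 3.16528e-5 * tk**3
    delta = 57.7 - 0.118 * tk
    return np.exp((b + 2.0 * delta) * p_atm / (R_GAS_CM3 * tk))


@dataclass(frozen=True)
class ConstantsSet:
    """A named, swappable set of CO2-system equilibrium constants."""

    name: str
    k0: Callable
    k1: Callable
    k2: Callable
    kb: Callable
    kw: Callable
    ks: Callable
    kf: Callable
    kp1: Callable
    kp2: Callable
    kp3: Callable
    ksi: Callable
    bt: Callable
    st: Callable
    ft: Callable
    cf: Callable


LUEKER_TOTAL = ConstantsSet(
    name="lueker00-total",
    k0=k0_weiss74,
    k1=k1_lueker00,
    k2=k2_lueker00,
    kb=kb_dickson90,
    kw=kw_millero95,
    ks=ks_dickson90,
    kf=kf_perezfraga87,
    kp1=kp1_millero95,
    kp2=kp2_millero95,
    kp3=kp3_millero95,
    ksi=ksi_millero95,
    bt=total_borate,
    st=total_sulfate,
    ft=total_fluoride,
    cf=fugacity_coefficient,
)

REGISTRY = {LUEKER_TOTAL.name: LUEKER_TOTAL}
DEFAULT_CONSTANTS = LUEKER_TOTAL
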