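"""Climate-CO2 separation of decadal changes in the pCO2 annual cycle.

The change in the monthly pCO2 anomaly between a modern and a future decade
is attributed on the Taylor basis to

* the change in sensitivities (the geochemical effect of higher atmospheric
  CO2, which erodes the buffer capacity),         sum_i  dg_i  X'_i0
* the change in driver anomalies (the radiative effect of physical climate
  change on the seasonal cycles of the drivers),  sum_i  g_i0  dX'_i
* and their synergy,                              sum_i  dg_i  dX'_i,

where the 0 subscript marks the modern decade and d the modern-to-future
change.  The three pieces sum exactly to the total Taylor-basis change; the
"starred" anomaly effect folds the synergy into the driver-anomaly piece,
which is how the separation is usually quoted: sensitivities alone scale the
existing cycle without moving its extremes, while the driver anomalies (plus
synergy) are what can reshape and re-time it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .taylor import DRIVERS, DriverAnomalies

__all__ = ["SeparationResult", "separate_climate_co2", "summer_enhancement"]


def _anom_dict(a) -> dict:
    if isinstance(a, DriverAnomalies):
        return {"T": a.Tprime, "S": a.Sprime, "AT": a.ATprime, "CT": a.CTprime}
    return {d: np.broadcast_to(np.asarray(a[d], float), (12,)) for d in DRIVERS}


def _gamma_dict(g) -> dict:
    return {d: np.broadcast_to(np.asarray(g[d], float), (12,)) for d in DRIVERS}


@dataclass
class SeparationResult:
    """The three attribution pieces, each a 12-month µatm series."""

    delta_sens: np.ndarray
    delta_anom: np.ndarray
    synergy: np.ndarray
    modern_total: np.ndarray
    future_total: np.ndarray

    @property
    def delta_anom_star(self) -> np.ndarray:
        """Driver-anomaly effect including the synergy with sensitivities."""
        return self.delta_anom + self.synergy

    @property
    def total(self) -> np.ndarray:
        """Total Taylor-basis change of pCO2' between the decades."""
        return self.delta_sens + self.delta_anom + self.synergy


def separate_climate_co2(
    modern_gamma, modern_anoms, future_gamma, future_anoms
) -> SeparationResult:
    """Attribute the modern-to-future change of pCO2' on the Taylor basis.

    All four inputs must share the same 12-month basis; sensitivities are
    per-month dicts keyed by driver, anomalies are `DriverAnomalies` or
    equivalent dicts.  Totals are Taylor reconstructions, not re-solved
    chemistry, so the additivity identity is exact.
    """
    g0 = _gamma_dict(modern_gamma)
    g1 = _gamma_dict(future_gamma)
    x0 = _anom_dict(modern_anoms)
    x1 = _anom_dict(future_anoms)
    delta_sens = np.zeros(12)
    delta_anom = np.zeros(12)
    synergy = np.zeros(12)
    modern_total = np.zeros(12)
    future_total = np.zeros(12)
    for d in DRIVERS:
        dg = g1[d] - g0[d]
        dx = x1[d] - x0[d]
        delta_sens = delta_sens + dg * x0[d]
        delta_anom = delta_anom + g0[d] * dx
        synergy = synergy + dg * dx
        modern_total = modern_total + g0[d] * x0[d]
        future_total = future_total + g1[d] * x1[d]
    return SeparationResult(
        delta_sens=delta_sens,
        delta_anom=delta_anom,
        synergy=synergy,
        modern_total=modern_total,
        future_total=future_total,
    )


def summer_enhancement(
    result: SeparationResult,
    summer_months,
    statistic: str = "extreme",
    reference: str = "absolute",
) -> float:
    """Percent enhancement of summer pCO2' from changed driver anomalies.

    Compares the summer statistic of the future state with all effects
    (modern + delta_sens + delta_anom*) against the counterfactual with the
    sensitivity change only (modern + delta_sens): the extra change that
    physical climate change contributes, as a percentage of the
    counterfactual summer statistic.

    statistic: "extreme" (maximum monthly value inside the summer window)
    or "mean" (summer average).  reference: "absolute" divides by the
    magnitude of the counterfactual statistic, "signed" by its signed value.
    """
    months = np.array(sorted(summer_months), dtype=int) - 1
    if months.size == 0 or months.min() < 0 or months.max() > 11:
        raise ValueError("summer_months must be a nonempty subset of 1..12")
    sens_only = result.modern_total + result.delta_sens
    full = result.modern_total + result.delta_sens + result.delta_anom_star
    if statistic == "extreme":
        a = full[months].max()
        b = sens_only[months].max()
    elif statistic == "mean":
        a = full[months].mean()
        b = sens_only[months].mean()
    else:
        raise ValueError("statistic must be 'extreme' or 'mean'")
    denom = abs(b) if reference == "absolute" else b
    if denom == 0:
        raise ValueError("counterfactual summer statistic is zero")
    return float(100.0 * (a - b) / denom)
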