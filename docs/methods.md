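# Methods

This note records the scientific and numerical choices behind `pco2season`:
what each stage computes, the defaults and their units, where the design was
genuinely open and what was decided, and what the synthetic tests do and do
not demonstrate about real data.

## Carbonate-system solver

The solver finds the total-scale [H⁺] closing the alkalinity balance

A_T = [HCO₃⁻] + 2[CO₃²⁻] + [B(OH)₄⁻] + [OH⁻] − [H⁺]_free
    + (phosphate alkalinity) + [SiO(OH)₃⁻]

for prescribed (T, S, A_T, C_T, P_T, Si_T). Minor pairs (NH₃, H₂S, and
HF/HSO₄⁻ beyond the total→free scale conversion) are omitted; at open-ocean
concentrations they contribute well below the reported residuals.

* **Constants** (registry `lueker00-total`, recorded in every output):
  K₁/K₂ Lueker, Dickson & Keeling (2000, total scale); K₀ Weiss (1974); K_B
  Dickson (1990b); K_W Millero (1995, handbook form); K_S Dickson (1990a,
  free scale, used only for scale conversion); K_F Perez & Fraga (1987);
  phosphate/silicate Millero (1995); totals B_T Uppström (1974), SO₄ Morris
  & Riley (1966), F Riley (1965). Alternates can be registered and swapped.
* **Root finding**: Newton in ln[H⁺] from pH 8, bracket maintained on
  pH ∈ [2, 12] with a bisection (geometric-mean) fallback whenever a step
  leaves the bracket; convergence |Δ[H⁺]|/[H⁺] < 10⁻¹², at most 100
  iterations; failures and bracket violations raise naming the offending
  state. The iteration is fully vectorized over numpy arrays, which is what
  makes century × grid × month sensitivity sweeps affordable (~10⁶ solves
  in seconds).
* **pCO₂** = [CO₂*]/(K₀ C_f), with the fugacity coefficient C_f from the
  Weiss (1974) virial form at 1 atm total pressure. Surface-only: no
  pressure dependence anywhere. Units are µmol kg⁻¹ at the API surface and
  mol kg⁻¹ internally; conversions live in one place.
* **Sensitivities** ∂pCO₂/∂X are central finite differences with fixed
  steps (T: 10⁻³ °C, S: 10⁻³, A_T/C_T: 0.1 µmol kg⁻¹); halving the steps
  changes results by < 10⁻⁴ relative. If a perturbed state leaves the valid
  range the step shrinks once (×0.1) before failing.
* **Closed-system thermal ratio.** (d ln pCO₂/dT)/(d ln [CO₂*]/dT) at fixed
  A_T = 2130, C_T = 2000 µmol kg⁻¹ was mapped over temperature: it is ≈7
  only near the freezing point (7.27 at −1.8 °C, 6.69 at 0 °C, falling to
  ~5.4 by 5 °C and ~3.4 at 20 °C), with weak salinity dependence. The
  package therefore quotes the ratio as a near-freezing polar-band average
  (T ∈ [−1.8, 0] °C, S ∈ [32, 34]), ≈ 7.0, rather than a single
  unexplained state.

## Detrending and climatologies

Monthly anomalies "relative to the annual mean" (primes) are computed by
subtracting a cubic-spline secular trend: annual means are computed per
year, a cubic spline is fit through them at each year's mean month-midpoint
position (365-day no-leap calendar) and evaluated at month midpoints, and
the difference is taken. With the default `lam=None` the spline interpolates
the annual means (they already average out monthly noise); a smoothing
penalty `lam` switches to `scipy`'s smoothing spline when interannual
wiggles in the annual means themselves should be suppressed. The knot
placement makes the removal exact for a linear trend; first/last years
carry natural-spline boundary effects and deserve less confidence. Fitting
the spline to annual means rather than to all monthly points is this
package's choice, documented here rather than asserted as the only reading.

Decadal climatologies are month-wise means over ten years, re-centred so the
twelve values sum to zero exactly — the defining property of an anomaly
relative to the annual mean. The summer-anomaly helper defaults to the
June/August/September window used for summer map averages, with a
contiguous June–July–August preset also provided; neither is silently
preferred, the window is always explicit in configs.

## Taylor decompositions

Terms are γᵢ[m]·X′ᵢ[m] with the "basic" weights γᵢ[m] = ½(monthly
sensitivity + annual-mean sensitivity) — the arithmetic mean, the simplest
reading of averaging the two, and a trapezoid-like linearization between
the annual-mean state and each month's state. P_T and Si_T are held in the
carbonate solves but excluded from the terms, so the reported closure error
honestly contains their (tiny) influence along with all second-order and
covariance effects. Closure — reconstructed minus directly solved p′CO₂ —
is carried on every `TermSeries` and never hidden; at the generator's
default amplitudes it sits just under 5 % of the seasonal amplitude, which
is the intrinsic size of the neglected second-order terms there, and it
grows monotonically as anomaly amplitudes are scaled up.

**Freshwater layout.** The A_T and C_T terms are each split into a
salinity-driven (freshwater: dilution/concentration by melt, precipitation,
rivers) part with coefficient s̄X/S₀ on S′, and a biogeochemical part
carrying the retained S/S₀ prefactor on the salinity-normalized anomaly
sX′ (sX = X·S₀/S, S₀ = annual-mean salinity of the cell; the prefactor is
kept because short-term salinity variations are large in ice-covered seas).
The biogeochemical part subtracts the constant cov(S′, sX′)/S₀; with that
closure constant the six terms regroup to the standard four-term total
*exactly*, month by month — the split is pure algebra, not a further
approximation.

**Incremental decade-to-decade form.** For strongly forced centuries the
basic approach closes poorly on the future decade, so the future
decomposition is built by accumulating consecutive-year increments from the
modern decade: each step contributes the pair-averaged sensitivity times
the anomaly increment *plus* the pair-averaged anomaly times the
sensitivity increment — together the exact discrete increment of the
product γX′. Without the conjugate term the accumulation drifts whenever
sensitivities trend, which is precisely the strong-forcing regime this form
exists for. Steps are weighted by averaging the ten telescoping paths that
connect equal within-decade offsets, so the accumulated change reproduces
exactly the change in the decadal mean of the per-year product; per-year
sensitivities use the same ½(monthly + that-year-annual) blend. With
constant sensitivities and linear drivers the whole construction telescopes
to the basic approach applied directly to the future decade. On the default
synthetic century the future-decade closure error of the incremental form
is less than half that of the basic form.

## Climate–CO₂ separation

Δp′CO₂ between the modern and future decades is split exactly into
Σ Δγᵢ·X′ᵢ₀ (changed sensitivities: the geochemical effect of higher CO₂),
Σ γᵢ₀·ΔX′ᵢ (changed driver anomalies: the radiative effect) and the synergy
Σ Δγᵢ·ΔX′ᵢ; the "starred" anomaly effect folds the synergy into the
driver-anomaly piece. Totals are Taylor-basis reconstructions, so the
three-way additivity is an exact identity, tested to machine precision.
The summer-enhancement statistic compares the summer extreme (or mean) of
the full future state against the counterfactual with only the sensitivity
change, as a percentage of the counterfactual; both the
absolute-magnitude and signed-reference variants are emitted because the
published convention is ambiguous, and the ensemble reports mean ± 1 s.d.
across members. On the synthetic ensemble this enhancement is large
(~160 % for the extreme) because the counterfactual summer extreme is
small there; its value is generator-specific and is not comparable to
multi-model archive numbers.

## Phenology

Months live on a circle. Timing series (month of annual high/low per CO₂
level) are phase-unwrapped before cubic-spline smoothing over the CO₂ axis
(default penalty 10⁴ on ppm abscissae) and mapped back into [1, 13).
Extremes break ties to the earliest month, and an all-flat cycle returns an
explicit degenerate result. Stages: (3) annual maximum inside the summer
window (default June–September); (2) a positive circular local maximum in
the window; (1) otherwise. **Crossover** is operationalized as the lowest
CO₂ level at which the smoothed basin series reaches stage 3 — equivalent
to the high/low timing curves crossing where both are well defined, and
robust when the low is indistinct; detection is invariant to constant
offsets, and smoothing choices move it by at most about one decadal level.
Basin timing uses area-weighted means of the variable first (de-emphasizing
ice-covered low-anomaly cells), whereas ice retreat/growth dates (first
crossing below/above 0.15 concentration) are computed per cell and the
month indices area-averaged, with never-crossing cells excluded; retreat at
or before July is flagged as the late-summer-transition diagnostic.
Debiasing subtracts the per-cell, per-month historical model bias against
an observational climatology from the future climatology before taking the
area-weighted shelf average of annual maxima.

## Grid

An idealized polar cap (default: 2° × 20° cells poleward of 70° N, shelf
ring shallower than 500 m equatorward of 78° N, deep basin poleward, no
land unless configured) stands in for a real gateway-bounded Arctic domain,
whose polygon is application data a user can supply as a mask. Cell areas
are exact spherical-zone weights; regridding is nearest-neighbour by
great-circle distance with masked sources excluded and an optional cutoff.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes — not
ocean physics. Per cell and month it builds:

* **Temperature**: latitude-graded mean (0.5 °C at the cap edge,
  −0.06 °C/°lat) + a small 1 °C seasonal cycle peaking in August (ice cover
  pins SST near freezing most of the year) + secular warming of 2.5 °C per
  CO₂ doubling (polar-amplified surface ocean) + a Gaussian summer bump
  (center month 7.5, width 1.5) proportional (5 °C per unit) to the
  *increase in March–August open-water fraction* relative to the first
  year — the solar-heating mechanism by which earlier ice retreat amplifies
  summer warming, which saturates naturally once ice is gone.
* **Ice**: a logistic function of monthly temperature against a
  latitude-graded freezing threshold (1.0 °C at the edge, +0.15 °C/°lat,
  width 0.5 °C), so retreat dates advance as the water warms and perennial
  ice at high latitude transitions to seasonal ice late in the century.
* **NPP**: a fixed-amplitude Gaussian bloom (peak month 7, width 1.5)
  whose peak advances by 0.5 month per month of earlier ice retreat.
* **C_T**: an annual mean of 2080 µmol kg⁻¹ at 284 ppm rising 0.20
  µmol kg⁻¹ per ppm of atmospheric CO₂ — an effective disequilibrium
  coupling chosen so mean surface pCO₂ tracks the atmosphere with realistic
  lag (≈335 µatm in the 2010s, ≈870 µatm in the 2090s under the RCP-like
  ramp) without solving air–sea exchange, which is out of scope; a seasonal
  bloom-drawdown/winter-resupply cycle equal to −20 µmol kg⁻¹ times the
  cumulative excess of NPP over its annual mean, so C_T peaks just before
  the bloom (April–May) and bottoms out just after it (Aug–Sep); and
  conservative dilution with salinity.
* **S and A_T**: base salinity 33 diluted by 0.8 per unit ice fraction
  melted in a month; A_T = 2230 µmol kg⁻¹ scaled conservatively with S/33.
* **Noise**: independent Gaussians per field/month/cell (σ: T 0.15 °C,
  S 0.05, A_T and C_T 4 µmol kg⁻¹, ice 0.02, NPP 0.05), all driven by one
  seed; fields are clamped to physical ranges.

These defaults place the modern decade in the observed Arctic regime —
basin p′CO₂ high in April, broad summer low carried by the C_T term,
|non-thermal| > |thermal| in summer — and under the default RCP-like ramp
(284 + 4.65·(e^{0.0198(t−1850)} − 1) ppm, ≈313 ppm in 1950 and ≈936 ppm in
2100) produce a stage 1→2→3 evolution with crossover near 560–610 ppm,
shelf cells flipping before the deep basin. Because warming and ice are
functions of the CO₂ level, not of time, the crossover level is consistent
across pathways of different steepness, as the analysis expects.

The **TruthRecord** is computed from the noise-free construction by direct
carbonate solves of exact basin-mean drivers — no detrending, no decadal
averaging, no smoothing — so pipeline estimates (which see noise, splines
and decadal sampling) are scored against an independent constructed answer.
Same seed, same bits: generation is fully deterministic.

**What passing these tests does not show.** The generator has sinusoid-plus-
bump seasonality, linear couplings with clamps, white noise, no advection or
mixing, no interannual modes, no model-structural diversity (ensemble
members differ only by noise seed), and drivers whose trends are smooth in
CO₂. Recovery here validates the machinery — chemistry, decompositions,
identities, phenology detection under noise and sampling — not the climate
realism of any particular number; statistics such as the crossover level or
the summer-enhancement percentage are properties of the emulated scenario,
not predictions, and real-archive values require real archives through the
same pipeline entry points (NetCDF with the generator's layout).

## Problem sizes and runtime

Defaults used throughout tests and the acceptance study: a 10 × 18 cell
polar cap (180 ocean cells), 151 years × 12 months, 15 decadal levels;
9-member ensembles for decomposition/separation statistics and 21 members
for phenology recovery. One full member takes a few seconds on one core;
the complete acceptance study about a minute. All sizes are configuration,
not code.

## Known limitations

* The alkalinity model omits minor acid-base systems; at hypersaline or
  anoxic extremes the omissions would matter.
* The basic-approach closure (~5 % of amplitude at default forcing) bounds
  how literally individual monthly term values should be read.
* Crossover is reported at decadal sampling resolution; the ±1-level
  recovery tolerance reflects that, not detector noise.
* The idealized polar-cap domain stands in for a gateway-bounded basin;
  area-weighted statistics over a user-supplied real mask are supported but
  untested against real geography.
* Debiasing is only as good as the supplied observational climatology and
  assumes additive, stationary model bias per cell and month.
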