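# Methods

This note documents the models implemented in `soilnflux`, the choices
made where the design was genuinely open, and what the synthetic
generator does and does not emulate.

## Chamber flux estimation

The measurement system is a well-mixed, vented automated chamber: the
NO analyzer consumes chamber air (it oxidizes NO with ozone and does not
return the sample), which is replaced by ambient makeup air at the
circulation flow Q. The forward mass balance is

    V dC/dt = F·A/κ + Q·(C_in − C),        κ = M/V₀ · P/P₀ · T₀/T

with C in nmol mol⁻¹ and κ the mole-fraction→mass conversion
(0.625 µg N m⁻³ per nmol mol⁻¹ for NO at 273 K, 1013 hPa). Its solution
rises with time constant τ = V/Q (≈30 min for V = 0.091 m³ and
Q = 3 L min⁻¹) toward C_in + F·A/(Q·κ). Because τ is comparable to the
closure length, neither the slope alone nor the steady offset alone
carries the whole flux; the hybrid estimator

    F̂ = [ dC/dt · V/A + (C̄_window − C_in) · Q/A ] · κ

sums both, and on noiseless forward-model closures the two terms
compensate to within ~0.1 % (NO window) and ~1 % (N₂O window) of the
true flux — the slope term decays like e^(−t/τ) exactly as the dilution
term grows like 1 − e^(−t/τ).

Choices:

* **Units.** Analyzer series are dry mole fractions; κ is applied once.
  An input that is already in µg N m⁻³ must not be passed through κ
  again (the estimator operates on nmol mol⁻¹ by contract).
* **Ambient reference.** The makeup-air concentration C_in is the mean
  of the 30-s post-opening segment; the chamber concentration C̄ is the
  regression-window mean. This sign convention makes the dilution term
  positive for an emitting soil.
* **M is grams of N per mole of gas** (NO 14, N₂O 28), so all fluxes are
  nitrogen mass.
* **Windows.** OLS slope over min 6–10 (NO) or 6–20 (N₂O); the first
  3 min are a lid-open line flush and never enter the regression.
* **QC.** A median-absolute-deviation spike filter (>5 MAD within the
  window) drops samples and flags the record; fewer than 4 usable
  samples yields a flagged record with missing flux; an optional minimum
  slope-R² is off by default.
* **Aggregation.** The treatment daily mean is the mean over chambers of
  chamber means (equal chamber weighting, robust to unequal closure
  counts). Chambers within a plot are pseudo-replicates; the reported SE
  across chamber means is a precision, not a plot-level inferential
  error.
* **Integration.** Daily means represent whole days, so cumulative
  flux = Σ daily × 24 h (2.4×10⁻⁴ kg N ha⁻¹ per µg N m⁻² h⁻¹-day).
  Interior gaps up to 7 days are linearly interpolated; longer gaps
  contribute zero and flag the value with its coverage. Annual NO
  applies a snow-cover rule (December–March treated as negligible);
  N₂O does not, since late-winter freeze–thaw emissions are real signal.

## Soil moisture

WFPS = VWC/(1 − BD/2.65)·100 with BD defaulting to 0.70 g cm⁻³ for the
0–10 cm mineral layer and 2.65 g cm⁻³ the quartz particle density. The
division convention follows the standard porosity formula. The organic
horizon is gravimetric (g H₂O g⁻¹) and has no WFPS; WFPS-based
operations accept mineral layers only. Supersaturated probe readings cap
at 100 % with a warning rather than an error.

## Response models

Temperature and moisture responses are fitted to **binned means**
(0.5 °C, 1 % WFPS), unweighted by bin counts (an n-weighted option
exists). The exponential fit is nonlinear least squares on the original
scale, initialized from a log-linear regression of the positive bin
means; Q10 = e^(10k) is stored from the fitted k so the identity is
exact. The quadratic moisture fit reports its vertex as an optimum only
when concave and interior to the fitted range. The Q10 counterfactual
F·Q10^(ΔT/10) composes exactly in ΔT and is applied at whatever
granularity the caller chooses.

## N₂ upscaling and net rates

Daily N₂ = max(0, 0.13·WFPS − 1.10)·F_N₂O. The ratio model deliberately
has **no temperature term** — a temperature-gradient incubation showed
moisture-driven regulation of N₂:N₂O with no temperature effect — and
its validity range defaults to the field-observed WFPS span (15–75 %),
warning outside it. Below the ratio root (WFPS ≈ 8.5 %) the ratio clamps
to zero; on N₂O-uptake days (negative flux) N₂ is set missing rather
than negative. The published N₂ budget is a growing-season quantity, so
`seasonal_n2` integrates May–October by default.

Net rates R_M and R_N come from one-week incubation pool changes and may
be negative (immobilization); extrapolation to field temperature uses
R = a·e^(bT) fitted over the 5–25 °C gradient, warning beyond ±5 °C of
it.

## Effect sizes and cross-study regression

lnRR guards its log transform (non-positive means → missing); RRn
standardizes to 1 °C of realized warming. Effect-size SEs use a seeded
1000-replicate bootstrap across sampling times, because only ±SE
summaries, not a resampling scheme, are conventionally reported. The
cross-study synthesis is an unweighted OLS of per-site RRn on ΔWFPS (%),
with the usual t-based slope p-value and no multiple-testing correction
(a single pre-specified predictor); it is not a variance-weighted
random-effects meta-analysis. The bundled
`data/synthetic_warming_sites.csv` is a **synthetic stand-in** site
table: ten simulated temperate-forest warming studies with plausible
covariates whose RRn–ΔWFPS relation is constructed (residuals
orthogonalized against the predictor and scaled) to have R² = 0.45
exactly. It exercises the schema and the regression machinery; replace
it with a transcription of a real site compilation for substantive use.

## The synthetic experiment

The generator emulates the study conditions of a temperate
monsoon-climate forest warming experiment; its defaults are those
conditions, not tuning knobs.

**Climate.** Day-of-year 1–365 calendar (no leap days), growing season
May–October. Mineral soil temperature = 10 + 15·cos(seasonal) °C
(range ≈ −5 to 25 °C, peak mid-July) plus AR(1) noise (sd 1.2 °C,
ρ = 0.8) per plot; the O horizon swings slightly wider. Precipitation is
a seasonally inhomogeneous event process (wet-day probability 0.35 and
gamma-distributed amounts averaging 12 mm in May–September, 0.15/5 mm
otherwise), giving ≈810 mm yr⁻¹ with >75 % in May–September and several
heavy (≥30 mm) events per season.

**Moisture.** Each layer is a bucket: gains from infiltrated rain and
snowmelt, losses from evapotranspiration proportional to temperature and
relative wetness; the mineral bucket drains to field capacity
(VWC 0.42) within a day, so WFPS peaks near 57 % after rain and averages
≈35 % in the growing season; the O horizon averages ≈0.81 g g⁻¹. Snow
accumulates while the soil is frozen and melts from the thaw date at
10 mm d⁻¹. Warmed plots receive +ΔT (default 2 °C) and a per-layer ET
multiplier **calibrated by bisection** so the realized growing-season
moisture deficit matches the configured targets (−16 % O horizon, −5 %
mineral); with null targets the calibration returns neutral forcing and
the treatment streams are bit-identical.

**Thaw.** The control thaw date is the seasonal 0 °C crossing; the
warmed date is advanced by a uniform 8–11-day draw scaled by ΔT/2
(so a null treatment has zero advance), rounded to whole days so the two
treatments' post-thaw grids align.

**Flux surfaces.** NO: A·e^(kT) (k = ln 3.5/10) × a downward parabola in
WFPS peaking at 35 % and clipped at zero. N₂O: A·e^(kT) (k = ln 2.1/10)
× an increasing moisture factor, plus a freeze–thaw pulse starting 2
days after thaw (soil rewetted to field capacity by then) and decaying
over ~5 days. Amplitudes are set so ambient annual budgets are ≈0.6
(NO) and ≈1.2 (N₂O) kg N ha⁻¹ y⁻¹ with ≈75 % of N₂O emitted in the
dormant season.

**Warming suppression.** The mineral-WFPS parabola alone is orders of
magnitude too weak to overturn a +28 % temperature effect, so the
surfaces carry a substrate-supply factor (θ_O divided by its ambient
seasonal climatology, raised to a species exponent: 2.4 for NO, 1.8 for
N₂O) representing moisture-limited N mineralization and nitrification
in the organic horizon. Anchoring to the ambient climatology keeps the
factor ≈1 in control plots — so ambient apparent Q10 is recovered
without bias — while O-horizon drying under warming shrinks it to
(1−0.16)^γ, reproducing warming responses of ≈−19 % (NO) and ≈−16 to
−20 % (N₂O). The freeze–thaw pulse draws on N mineralized before winter,
so its supply factor uses the *preceding growing season's* moisture
status, and its temperature factor references thaw stage plus the
treatment's warming offset rather than the calendar; both choices make
the no-drying limit reduce exactly to the pure Q10 expectation.

**Measurement.** Each chamber carries a persistent unit-mean lognormal
heterogeneity factor (sd 0.15); each closure is forward-modelled in
closed form with white analyzer noise (0.2 nmol mol⁻¹ NO,
0.5 nmol mol⁻¹ N₂O) and estimated by the same code path as field data.
Ambient mole fractions default to 1 (NO) and 330 (N₂O) nmol mol⁻¹ —
conventional values, exposed in the config. Substreams are keyed by
(purpose, plot id, chamber, species), so enlarging the design never
perturbs existing series.

**Incubations.** Before/after NH₄⁺/NO₃⁻ pools at 5–25 °C follow
R = a·e^(bT) (b = ln 2/10) with six replicates; warmed O-horizon soils
carry rate multipliers 0.79 (R_M) and 0.86 (R_N) and mineral soils none,
mirroring the field contrast. Moisture is held at its initial value, as
in the laboratory protocol this emulates.

**What the generator does not emulate.** Sub-daily temperature and flux
dynamics (closures within a day share the daily state), soil
heat transport, mechanistic evapotranspiration, plant N uptake, snowpack
physics beyond a threshold store, analyzer drift, and chamber artifacts
(pressure pulses, leaks, nonlinearity). Passing tests therefore show the
*estimators and statistics* behave correctly under realistic structure
and noise — not that any particular field site obeys these surfaces.

## Problem sizes and numerics

Default simulations span 2 years × 6 plots × 5 chambers × 4 closures per
day at 10-s sample resolution; seed-ensemble checks (parameter recovery,
direction of effect) use 10–20 seeds and 1–2 year runs. Nonlinear fits
use `scipy.optimize.curve_fit` with log-linear initialization and
parameter tolerances of 1e-12; non-convergence raises an error carrying
the initializer estimates. Bins are left-closed/right-open; empty bins
drop. All randomness flows from the config seed through named
`SeedSequence` substreams; no stage reads the wall clock.

## Known limitations

* The hybrid estimator assumes a well-mixed headspace and constant flux
  over the closure; nonlinear (HMR-style) closure models are out of
  scope.
* The N₂:N₂O ratio model was calibrated off-site in the study this
  emulates; its validity range is configurable but the default is an
  assumption.
* The ΔWFPS unit in the cross-study regression (percent vs fraction) is
  configurable via the predictor column; results echo the unit used.
* Treatment SEs are computed across chamber means and understate
  plot-level uncertainty with n = 3 plots per treatment.
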