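# Methods

This note documents the models, numerical choices and defaults behind
`sedflux`, and what the synthetic-data tests do and do not demonstrate
about real sensor data.

## Coordinate and sign conventions

Depths are in millimetres, zero at the sediment–water interface, positive
downward; negative depths are overlying-water readings. The interface
position is taken from the recorded zero of the profiling rig and never
re-detected from profile shape — operators set the zero visually or from
the O2 break during measurement, and second-guessing it would silently
shift every derived depth. Concentrations are in μM (= mmol m⁻³), fluxes
in mmol m⁻² d⁻¹, diffusivities in m² d⁻¹ (1 cm² s⁻¹ = 8.64 m² d⁻¹).
Because gradients are fitted on the depth-down axis, Fick's law gives
sediment uptake a negative sign (O2 decreases downward) and upward efflux
a positive sign (ΣH2S increases downward) without any extra sign handling.

## Sulfide speciation

ΣH2S = [H2S]·(1 + 10^(pH − pK1)) at each depth, with pH linearly
interpolated onto the H2S grid (the two chemical sensors share a nominal
250 μm grid but real grids can be offset). The default pK1(T, S) is the
Millero (1988) seawater fit

    ln K1 = 225.838 − 13275.3/T − 34.6435 ln T + 0.3449 √S − 0.0274 S

(T in kelvin), valid for 0–40 °C and S 0–40, reproducing the tabulated
6.98 (fresh water) and 6.51 (S = 35) at 25 °C. pH electrodes calibrated
against commercial NBS buffers are assumed and no pH-scale conversion is
applied; users reproducing a calculation made with a different constant or
scale can pass `pk1_override`. The second dissociation to S²⁻ is
negligible at porewater pH and not modelled. Negative H2S readings are
clipped to zero before speciation (the quantity is physically
non-negative) and counted in diagnostics; raw readings are preserved for
everything that is noise-sensitive (see horizon detection).

## Horizon detection

The OPD is the shallowest depth below which O2 stays steadily < 1 μM; the
sulfide horizon the shallowest depth below which sulfide is steadily
> 1 μM. "Steadily" defaults to the terminal-run rule — every deeper
measured point must qualify — which is the strictest reading and makes a
single sub-threshold dip with recovery non-detections. The crossing is
refined by linear interpolation between the last disqualifying point and
the first point of the qualifying run, so noise-free detection returns the
analytic threshold crossing of the underlying shape to sub-grid precision.

Two caveats follow directly from the threshold definition:

* A 1 μM threshold detector cannot resolve the true zero of a profile
  better than the threshold offset: for a parabolic O2 profile the 1 μM
  crossing sits OPD·√(1 μM / C0) above the true zero (up to ~0.13 mm at
  C0 = 300 μM), and for a linear sulfide ramp 1 μM/gradient below the true
  onset. These offsets are closed-form and accounted for in the accuracy
  tests; they are smaller than between-replicate scatter in practice.
* With realistic sensor noise (≈2 μM) the threshold sits at ~0.5 σ and the
  strict terminal-run rule breaks down (noise in the anoxic zone exceeds
  1 μM roughly every third point). For noisy traces the pipeline therefore
  (a) applies a centred 5-point moving average before detection, (b) uses
  a persistence rule of 3 consecutive qualifying points, and (c) detects
  the sulfide horizon on the *raw, unclipped* [H2S] signal rather than on
  ΣH2S — speciation multiplies sensor noise by 1 + 10^(pH − pK1), a factor
  of up to ~8 in the high-pH surface layer, whereas the raw signal carries
  uniform noise; clipping first would bias the anoxic-zone noise mean to
  +0.8 σ, right against the threshold. In addition the sulfide detector
  supports a two-stage "anchored" mode (default in the pipeline): locate
  unambiguous strong signal (> 5 μM, smoothed), then report the 1 μM
  crossing of the contiguous detectable run containing that anchor,
  evaluated on unsmoothed readings (a moving average smears the onset ramp
  upward by half the filter width). Isolated noise excursions not
  connected to the strong signal then cannot fake a horizon. These
  settings were chosen by measuring detector bias and false-positive rates
  on simulated noise and are all configurable; noise-free analyses use the
  plain terminal-run rule.

The oxidized (sulfide-free) sediment volume per unit area equals the
sulfide horizon depth, so treatment contrasts in oxidized volume are
reported as relative horizon changes; the suboxic separation zone is the
difference between horizon and OPD, with negative widths flagged as
overlapping zones rather than clamped.

## Diffusivities and fluxes

Fluxes follow J = −φ (Ds + Db) ∂C/∂x with Ds = φ²·Dmol exactly as
written; a `flux_convention="no_outer_porosity"` switch drops the leading
φ for users of conventions that fold porosity into the gradient. Dmol
defaults come from infinite-dilution fits to the standard seawater
compilation — O2: (11.70 + 0.344 T + 0.00505 T²)·10⁻⁶ cm² s⁻¹; ΣH2S uses
the HS⁻ fit (10.40 + 0.273 T)·10⁻⁶ cm² s⁻¹, HS⁻ being the dominant
species at porewater pH near or above pK1. No explicit salinity
correction is applied (a few percent over the brackish–marine range,
small against porosity and Db uncertainty); any value can be overridden
per solute in configuration, in cm² s⁻¹ or m² d⁻¹.

Biodiffusivity Db is a linear function of meiofauna abundance
(individuals per 10 cm²), fitted by OLS to (abundance, Db) reference
pairs and clipped at zero. The package ships a clearly-labelled
**synthetic placeholder** calibration spanning transport enhancements
(Ds+Db)/Ds of ~1.1–2, the range published for meiofauna-reworked surface
sediments; it exists so the machinery is runnable out of the box, not as
a measured calibration. Real analyses should supply their own reference
points or disable Db (`d_b = 0`) for the pure molecular-diffusion case.

Gradients are fitted by ordinary least squares over recorded windows:
O2 from the interface to 60% of the OPD (the quasi-linear diffusive
zone; deeper points curve toward the zero-gradient landing and flatten
the slope), ΣH2S over the first 1.0 mm below the sulfide horizon. Both
windows are configurable and echoed into output for auditability; an r²
below 0.8 flags a warning rather than failing. For the parabolic
constant-consumption O2 shape the window bias is exactly closed-form: the
OLS slope of evenly spaced points on [0, w] equals the interface gradient
times (1 − w/(2·OPD)), for any number of points ≥ 2 — the basis for the
window-corrected comparisons in the recovery tests
(`parabolic_window_attenuation`).

## Oxygen budget

O2-equivalent of the sulfide efflux: −stoichiometry · J_H2S, default
stoichiometry 2 (complete oxidation to sulfate). Fractions are computed on
unrounded fluxes and additionally presented rounded to integer percent.
Fractions above 100% (possible with noisy inputs) set an inconsistency
flag instead of clamping, preserving their diagnostic value. A downward
(negative) sulfide flux is outside the budget's model and is a hard error.

## Synthetic data

The generator emulates a three-week incubation of cores from a seasonally
hypoxic, brackish (S = 7), 8 °C coastal basin along an imposed meiofauna
abundance gradient (means 128 / 191 / 828 / 2030 ind. per 10 cm²):

* O2: C(z) = C0·(1 − z/L)² down to the OPD L, zero below, C0 in the
  overlying water; C0 ~ U(300, 330) μM, L per treatment and week in
  0.8–2.3 mm. The parabola is the steady state of constant volumetric
  consumption and has an analytic interface gradient −2·C0/L, so truth
  fluxes are closed-form — the reason it was chosen over an exponential.
* ΣH2S: zero above the horizon (3.2–6.4 mm by treatment and week),
  rising linearly below with a gradient set so the implied Fick flux hits
  a per-treatment target (8.8 / 2.9 / 4.4 / 0.4 mmol m⁻² d⁻¹ in week one,
  converging over weeks two and three). The sensor-level [H2S] is
  back-computed as truth / (1 + 10^(pH − pK1)), making the speciation
  round trip exact by construction in the noise-free case.
* pH: monotone PCHIP decline from 7.6–7.9 at the interface to 5.4–7.2 at
  depth, plus an optional additive Gaussian bump for the oxic-zone pH
  maximum produced by electrogenic sulfur oxidation (default example:
  pH 8.3 at 0.75 mm, σ = 0.3 mm, appearing in the high-abundance cores in
  week one and faintly in control cores later). The bump amplitude is set
  so the peak value is met exactly at the peak depth; only the signature's
  geometry is modelled, not its electrochemistry.
* Noise: i.i.d. Gaussian per point, added last (defaults 2 μM on O2 and
  H2S, 0.02 pH units — typical microsensor repeatability), with readings
  floored at −5 μM as a sensor-output clamp. There is no drift,
  no irrigation/burrow fine structure, no replicate-to-replicate
  micro-heterogeneity beyond the noise, and no transient dynamics: the
  between-core lognormal variability (CV 5%) and the weekly parameter
  trajectories are imposed, not emergent.

Consequently, passing recovery tests show that the analysis chain is
*self-consistent and unbiased for diffusion-shaped steady-state profiles
with white noise*; they cannot show robustness to real-sediment features
the generator omits (drift, spatial heterogeneity, non-steady-state
profiles, DBL variation).

## Accuracy, measured

On 100 simulated cores spanning the conditions above (porosity
U(0.85, 0.93), sulfide flux targets U(0.4, 8.8) mmol m⁻² d⁻¹, abundances
U(100, 2100)):

* noise-free: recovered fluxes match truth to ~10⁻¹⁴ relative (O2 after
  the closed-form window attenuation), detection returns the analytic
  threshold crossings to sub-grid precision, and the speciation round
  trip is exact to ~10⁻¹³ μM;
* with 2 μM noise and 3 replicate profiles averaged: O2 fluxes recover
  within ~1–2% per core; sulfide fluxes within ~4% median. Per-core
  sulfide accuracy is noise-floor limited at the low end: a 0.4
  mmol m⁻² d⁻¹ flux over a 2 mm fit window cannot beat ~25% relative
  error at this noise level (consistent with the ±25% such fluxes carry
  in field reports), which is why noisy sulfide accuracy is summarised by
  the median. The noisy benchmark fits the deep gradient over 2 mm
  (9 points) rather than the 1 mm pipeline default, trading no bias (the
  profile is linear below the horizon) for ~2.4× less slope noise.

These numbers are recomputed, not asserted from memory, by
`python scripts/acceptance.py` and the test suite.

## Pipeline and aggregation

The pipeline computes every quantity per profile replicate, then
aggregates mean ± standard error (sample SD/√n) across the 3 replicate
profiles of a core, then across the 3 cores of a treatment, so a
treatment mean summarises n = 9 profile fits. Single values report their
SE as absent rather than zero; no profile is silently dropped — every
input profile appears in the per-profile table with values or a flagged
failure reason. Inference statistics (ANOVA, post-hoc tests, ordination)
are deliberately out of scope: the pipeline ends at descriptive
aggregates, and standard tools take over from the CSV output.

## Known limitations

* The Db–abundance model is linear with a synthetic default calibration;
  nonlinear or saturating bioturbation responses are not representable.
* No diffusive-boundary-layer model: fluxes are sediment-side only and
  assume the recorded interface zero is correct.
* No inverse reaction–transport modelling (production/consumption depth
  distributions), no irrigation/non-local exchange, no transient fluxes.
* The pK1 formulation and NBS-scale assumption introduce a systematic
  uncertainty of a few hundredths in pK1; `pk1_override` exists for exact
  reproduction of alternative choices.
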