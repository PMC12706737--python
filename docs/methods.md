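# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## Congener properties

All 209 PCB congeners are organized into 173 chromatographic peaks (the
resolution of congener-specific GC-MS/MS on an octyl-type column).
Coeluting congeners share one peak and are assigned the property values
of the **lowest-numbered member** — a deterministic convention chosen
because the measurement cannot apportion mass within a peak anyway.

The shipped default table is a synthetic stand-in built from smooth
homolog-based correlations (one value per congener, with a small
within-homolog spread), not a transcription of any single compilation;
it carries a `provenance` column saying so, and any user table with the
same columns replaces it everywhere. Anchors:

| property | form | anchor rationale |
|---|---|---|
| MW (g mol⁻¹) | 188.7 + 34.444 (n<sub>Cl</sub> − 1) | biphenyl + Cl-for-H increments |
| H₂₉₈ (Pa m³ mol⁻¹) | 10^(1.80 − 0.045 n<sub>Cl</sub> + 0.08 f) | the higher experimental (gas-stripping) measurement scale, ~40–50 for di/tri/tetra congeners |
| ΔU<sub>aw</sub> (J mol⁻¹) | 47 000 + 1 800 n<sub>Cl</sub> | typical 50–65 kJ mol⁻¹ range |
| log K<sub>OA,298</sub> | 6.35 + 0.53 n<sub>Cl</sub> + 0.15 f | ~7.9 for tri-CBs, ~11.9 for deca |
| molar volume (cm³ mol⁻¹) | 184.6 + 20.9 n<sub>Cl</sub> | LeBas additivity |

(f = centred position within the homolog, −0.5…0.5.)

Henry's law constants are temperature-adjusted by the van 't Hoff form
H(T) = H₂₉₈·exp((ΔU<sub>aw</sub>/R)(1/298.15 − 1/T)) and made
dimensionless as H′ = H/(RT).

Aroclor 1016 and 1242 reference profiles are synthetic reconstructions
(filenames carry `_synthetic`): published homolog weight compositions
distributed across peaks with characteristic light-Aroclor congeners
upweighted 4:1. They are adequate as similarity-analysis fingerprints;
substitute measured profiles for source-apportionment work.

## Two-film flux

Flux is gross volatilization, F = V·C, with C the truly dissolved
concentration (pg L⁻¹ ≡ ng m⁻³) and no air-side back-partitioning term;
F ≥ 0 always. The overall velocity combines film velocities in series.

* Water side: k<sub>ref</sub>(u₁₀) = a₂u² + a₁u + a₀ at Sc<sub>ref</sub> = 660,
  scaled by (Sc/660)^(−1/2). Schmidt numbers come from Hayduk–Laudie
  aqueous diffusivities and a standard water-viscosity correlation.
* Air side: k<sub>a,H₂O</sub>(u₁₀) = (0.2u + 0.3) cm s⁻¹, scaled by
  (D<sub>i</sub>/D<sub>H₂O</sub>)^0.61 with Fuller air diffusivities.

**Coefficient sets are config, not constants.** The default
(`calibrated`: a₂ = 1.0, a₁ = 1.5 m d⁻¹) was set — once, as a design
choice — so that the overall ΣPCB velocity under the package's default
August meteorology is ~3 m d⁻¹, reproducing harbor-scale reported
volatilization fluxes of several hundred ng m⁻² d⁻¹ from ~100 pg L⁻¹
water. This is deliberately faster than open-water dual-tracer
gas-exchange coefficients (shipped as the `nightingale2000` preset,
which yields ~6× lower water-side velocities and correspondingly lower
fluxes): harbor-scale flux studies in this domain report overall
velocities in the m d⁻¹ range that the dual-tracer set cannot produce at
3–9 m s⁻¹ winds, and with the default H scale the velocity is largely
air-side-limited anyway. Users comparing against open-ocean work should
switch presets; the two presets bracket the plausible range.

Velocities are computed **hourly and then averaged** over the analysis
window — wind enters quadratically, so averaging the met first would
bias fluxes low. Hours with u₁₀ = 0 under a zero intercept contribute
zero water-side transfer.

Worst-case concentration = per-peak mean of the k = 3 samples with the
highest ΣPCB totals (ranking by totals, not per-congener maxima).
Emissions: E = F × area × 10⁻⁹/86 400 (g s⁻¹), default area 1.5×10⁷ m².

Monte Carlo (default 10 000 iterations, seed required): concentrations
get multiplicative lognormal noise (0.3 natural-log sd, the replicate
spread of the synthetic generator), Henry's law constants ±20 %
lognormal, and met hours are bootstrap-resampled; reported as per-peak
and ΣPCB mean ± sd.

## Gaussian plume

The emitting polygon is discretized into ground-level cells (default
250 m; a grid-convergence test holds changes under 2 % at half the
size). Each cell contributes the reflected ground-source kernel
Q/(π σy σz u)·exp(−y²/2σy²)·exp(−z²/2σz²). Stability comes from a
Turner-style day/night + wind lookup (split classes resolved to the more
stable letter; overcast forces D), σy/σz from Briggs interpolation
formulas, urban coefficients by default. Choices that matter:

* calm threshold 0.5 m s⁻¹ — the kernel diverges as u→0, so calm hours
  are excluded from period averages and counted in the QC log;
* cells closer than half a cell downwind of a receptor are skipped,
  which removes the self-cell singularity for receptors on or in the
  source;
* coordinates are local projected metres; the default source is a
  26.5 km × 0.57 km rectangle (15 km²) along the y axis.

This is an order-of-magnitude screening model: no boundary-layer
similarity theory, terrain, downwash, or deposition.

## PUF–PAS inversion

K′ (PUF–air partition capacity per unit PUF volume) uses
log K<sub>PUF</sub> (m³ g⁻¹) = 0.6366 log K<sub>OA</sub> − 3.1774 with
PUF density 21 kg m⁻³, temperature-adjusted with
ΔU<sub>OA</sub> = 9 000·log K<sub>OA</sub> J mol⁻¹ (a van 't Hoff analog;
the effect is small over deployment-mean temperatures). Effective volume
and DC sampling rate are the exact inverse of each other, and a
noiseless forward–inverse round trip is identity to machine precision
(tested).

Depuration-compound estimates are valid only for 20–80 % loss; outside
the window the estimate is returned but flagged, and the pipeline falls
back to a configurable model sampling rate (default 4.9 m³ d⁻¹).
Recovery correction divides by surrogate recovery only when recovery is
below 100 %. The LOQ is the upper one-sided 99 % confidence limit of the
mean log₁₀ blank mass, back-transformed — a confidence interval, not a
prediction interval (the narrower of the two readings of that rule; the
choice is isolated in one function). Below-LOQ peaks are reported as 0
and flagged; ΣPCB sums quantified peaks only.

## Statistics

* Cosine similarity is computed on the 173-peak basis; profiles on
  mismatched peak sets are intersected and renormalized with a warning.
* Distance regression: OLS of concentration on log₁₀(distance to the
  source polygon boundary); a constant response reports R² = 0.
* Moran's I uses row-standardized inverse-distance weights with no
  cutoff (documented and swappable — the weight scheme is a genuine
  free choice); expectation −1/(n−1); permutation p is one-sided for
  positive autocorrelation, (1 + #{I* ≥ I})/(n_perm + 1).
* Ordinary kriging: empirical semivariogram binned to one-third of the
  maximum separation (distant pairs have huge counts but no structural
  information), exponential model fitted by Cressie-weighted least
  squares, kriging weights constrained to sum to one; leave-one-out R²
  and RMSE reported. Single-realization variogram recovery at n = 100 is
  inherently variable — parameter tests fix seeds and should be read as
  "the estimator is unbiased enough", not as a guarantee for any one
  field.
* Rank-sum: exact two-sided p by full enumeration of rank assignments
  for combined n ≤ 12 (midranks for ties), tie-corrected normal
  approximation above.
* Co-located replicate samplers are collapsed to location means before
  any spatial statistic (inverse-distance weights are undefined at zero
  separation).

## Synthetic generator: what it emulates, and what it does not

Defaults encode the study conditions the pipeline targets: 21 water
samples at 7 sites, ΣPCB totals uniform in 80–184 pg L⁻¹, 48 % of mass
on the silicone-byproduct peaks (PCBs 44+47+65, 45+51, 68; split
0.5/0.3/0.2 within the component) with the remainder shaped like
Aroclor 1242; 40 days of hourly met with 23 °C daily-mean sinusoidal
temperature, Weibull (shape 2) winds whose scale is bisected so the
3.60–8.80 m s⁻¹ band holds ~33 % of hours (the light-wind branch of the
two solutions), water temperature as a 24 h trailing mean of air;
28 PUF deployments (two triplicate locations), 25 ng DC spikes,
sampling rates spread 1.4–7.6 m³ d⁻¹ across sites, 5 blanks with a
peak-specific lognormal floor spanning orders of magnitude, recoveries
Normal(0.88, 0.13) truncated to (0, 1.5]. "Measured" air is the plume's
water contribution plus an Aroclor-shaped urban component whose total is
lognormal (geometric mean 330 pg m⁻³) with a gentle power-law decay
toward the water (exponent 0.314, giving roughly a 4× near/far median
contrast). Within-site water variance is not reported in this domain's
monitoring data; the 0.3 log-sd noise default is a config knob.

Not emulated: instrument response and chromatography, storm-event
concentration dynamics, directional micrometeorology at sheltered
sampler sites, multiple discrete urban point sources, and terrain
channeling of wind. Passing tests therefore demonstrate internal
consistency of the inference chain under realistic magnitudes — not
that any particular real harbor matches the defaults.

## Problem sizes

The default test suite and the acceptance script run the full chain at
960 met hours, 173 peaks, 28 receptors, 250 m source cells, 10 000
Monte Carlo iterations and 999 permutations — about half a minute end to
end; unit tests use smaller cuts (single hours, 300–1 000 iterations)
chosen for tightness of the closed-form comparisons rather than speed.

## Known limitations

* The calibrated water-side coefficients are a scale choice, not a
  mechanistic fit; flux magnitudes inherit their ~±30 % ambiguity.
* The plume stand-in has no convective boundary-layer physics; nocturnal
  stable-class predictions are the least trustworthy.
* Below-LOQ substitution by zero biases ΣPCB low at clean sites;
  LOQ/2 substitution would be a one-line change.
* Property values for coeluting peaks ignore within-peak composition.
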