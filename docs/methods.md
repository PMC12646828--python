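# Methods

This note documents the models, numerical choices and limitations of
the package: what the synthetic generators emulate, how each biomarker
is defined and estimated, and where design decisions were genuinely
open.

## Synthetic B-mode frames

### Scene model

Frames are 8-bit grayscale grids with row 0 at the skin surface and
depth increasing with the row index. Vertical distances use the depth
calibration `row_calib` (cm/px), horizontal distances `col_calib`; the
default is isotropic 0.01 cm/px on a 450×512 frame (4.5 cm depth,
matching typical musculoskeletal preset depths of 4.5–4.7 cm). Bit
depth and calibration are conventions of this simulator, not values
inferred from any clinical dataset.

A transverse scene stacks, top to bottom: a bright skin band (default
0.06 cm at grey 240), a darker subcutaneous fat layer of thickness
`sft_cm` (grey 45), and an elliptical muscle belly whose top touches the
fat layer. ROI pixels are assigned to three echogenicity classes — low
(muscle surrogate), medium (fat surrogate), high (fibrous/artefact
surrogate) — with mean intensities 60/130/220, chosen to be separable by
a 3-class Otsu partition under the default speckle. Class geometry
comes from rank-thresholding a spatially correlated Gaussian random
field (white noise smoothed at `corr_length_px`, default 4 px) at the
planted fractions: the lowest-field n₁ pixels become class 0, the next
n₂ class 1, the rest class 2. Rank assignment makes the realized
fractions match the planted ones to within one pixel of rounding, which
is what lets planted-fraction recovery be asserted tightly; it makes no
claim about real tissue histology.

A longitudinal scene has the skin band, the fat layer, two bright
aponeurosis bands (3 px) whose centre-to-centre distances equal the
planted SFT and muscle thickness, and fascicle lines (grey 170, ~1.5 px
wide, default spacing 12 px) inclined at the planted pennation angle to
the exactly horizontal lower aponeurosis. The pennation angle is
defined physically: under anisotropic calibration the pixel-space slope
is tan(θ)·col_calib/row_calib.

Default scene parameters are the cohort-typical values used throughout
the package (SFT 0.77 cm, muscle thickness 0.98 cm, ellipse
0.49 × 2.01 cm giving RFMA ≈ 3.1 cm², class fractions
46.55/39.29/14.16%, pennation 5.32°).

### Speckle model

Noise is multiplicative unit-mean Rayleigh (scale σ = √(2/π)), the
standard fully-developed-speckle envelope, applied to the whole frame.
Two knobs control it: `speckle_scale` blends linearly between noise-free
(0) and full Rayleigh contrast (1, default), and `speckle_grain_px`
(default 1.5 px) smooths the envelope at the resolution-cell scale.
The grain is what gives speckle its characteristic texture in real
B-mode images, where the envelope is correlated over the point-spread
function rather than pixel-independent; it also keeps the three
intensity classes statistically separable, which the scene design
requires. Smoothing preserves the unit mean, so class means are
unbiased. Determinism is strict: all randomness flows from the explicit
scene seed through one `numpy` generator; identical parameters and seed
give bit-identical frames.

What the simulator does *not* emulate: physics-based wave propagation,
attenuation and time-gain compensation, anatomical curvature of layers,
JPEG compression artefacts, probe pressure deformation. Passing
recovery tests on these scenes therefore demonstrates correctness of
the measurement code under controlled conditions, not clinical accuracy
on real images.

## Echogenicity biomarkers

The ROI grey-level histogram uses 256 bins, one per 8-bit level. The
multilevel Otsu search maximises the between-class variance
σ²_B = Σₖ ωₖ(μₖ − μ_T)² over all strictly increasing threshold tuples,
equivalently Σₖ Sₖ²/Wₖ with Sₖ, Wₖ the class intensity sum and mass.
The implementation is exact (a backward dynamic programme over class
boundaries plus greedy reconstruction), not a heuristic, and is checked
against exhaustive enumeration in the tests. Conventions the histogram
method itself does not dictate, fixed here once:

- classes are half-open intervals [tₖ, tₖ₊₁): a pixel equal to a
  threshold belongs to the upper class;
- ties in σ²_B break to the lexicographically smallest tuple;
- thresholds are recomputed per image, never pooled across a cohort;
- a histogram with fewer distinct populated levels than classes is an
  error, not a silent degenerate answer.

MiT/FATiT/NMNFiT are the low/medium/high class percentages of the ROI;
their sum is 100 up to float rounding on every input. The
muscle/fat/other readings of the three classes are surrogate labels
only.

## Morphometry

RFMA is the ROI pixel count times the pixel area. RFMT is the maximum
over columns of the contiguous vertical extent of the mask — the
maximal anteroposterior diameter, the conventional transverse
measurement axis; central-axis thickness would be a defensible
alternative, and the choice matters only for concave masks. RFMAI is
RFMA/height², adopted by analogy with BMI/ASMI and consistent with the
cohort means it is calibrated against (3.10 cm²/1.62² m² ≈ 1.18).
Area and thickness depend on the mask only, never on intensities, and
scale linearly/quadratically with calibration. Masks touching the frame
border (incomplete capture) are measured as-is on the visible area and
flagged `truncated`.

SFT detection: the column-averaged intensity profile over the central
third of columns is smoothed (Gaussian, σ = 1 row); bands are
contiguous runs above half the floor-to-maximum range, located at their
intensity-weighted centroid (robust for plateau-shaped bands such as a
skin line flush with row 0). The two shallowest band centres are the
skin line and superior aponeurosis; fewer than two bands is a detection
failure (e.g. a zero-thickness fat layer merges them).

Pennation: the dominant fascicle orientation is the angle whose shear
(shifting each column by tan θ · col, linear interpolation) maximises
the variance of the ROI's row-mean profile — a projection-based
orientation response. The search is coarse (0.25° over ±31°) then fine
(0.02° over ±0.3°). The lower aponeurosis orientation is a line fit to
the per-column brightest rows in a thin window below the ROI (0° when no
band stands out). The reported angle is the absolute difference. A flat
response (no line structure, e.g. constant ROI) is a detection failure.
This estimator is this package's own; the contract is accuracy against
the planted angle (±0.5° noiseless, ±1° under default speckle), not
equivalence to any particular clinical tool.

## Scores and classification

Cut-offs for the mass/quality scores are per-sex medians (even n: mean
of the two central order statistics). They can be recomputed from any
cohort or taken from the published reference values shipped in
`sonomyo/data/published_cutoffs.yaml`; provenance is recorded either
way. Inequalities are strict exactly as published: values at the
cut-off score zero points. Missing inputs raise an error naming the
fields — a missing indicator is never silently scored 0.

EWGSOP2: low strength is handgrip < 27 kg (men) / < 16 kg (women); low
mass is ASMI < 7 / < 5.5 kg/m². Sarcopenia requires both; low strength
with preserved mass is probable sarcopenia. Dynapenia is operationalised
as low strength regardless of mass, so the sarcopenic are a subset of
the dynapenic.

Derived anthropometry: BMI = weight/height²; percent weight loss =
(usual − current)/usual × 100, negative for gain.

## Synthetic cohorts

Each sex is drawn from a multivariate Gaussian over 16 variables with
means/SDs set to the reference cohort moments (male n-fraction
295/647); height (1.70 ± 0.07 m men, 1.58 ± 0.06 m women) and percent
weight loss (8 ± 5%) are realistic assumptions for an older
malnutrition-risk population, as they are not part of the printed
moments. Gaussian marginals are an assumption — only means and SDs are
known, skewness is not. Physiological non-negativity is enforced by
resampling offending rows (rejection), which perturbs the calibrated
moments negligibly at the default parameters.

Internal consistency is structural rather than sampled:

- phase angle = arctan(reactance/resistance)·180/π (at the female mean
  inputs this gives 4.78°, matching the printed 4.79°); note the
  *sample mean* of the derived phase angle sits slightly above the
  plug-in value because the arctan of a ratio is convex in the
  denominator;
- NMNFiT = 100 − MiT − FATiT; rows whose residual would be negative
  (a few percent at default moments) are clamped to 0 with MiT/FATiT
  rescaled to keep the closure exact;
- RFMAI = RFMA/height²; current weight = BMI·height²; usual weight from
  the percent loss.

Default correlations, all others zero unless configured:

- corr(RFMT, RFMA) = 0.93. Derivation: if both indicators are
  median-dichotomised bivariate-normal latents, P(both below median) =
  1/4 + asin ρ/2π. The published mass-score distribution has 44%
  scoring 2 points, so ρ = sin(2π(0.44 − 0.25)) = 0.930.
- Quality latent equicorrelation 0.39: for an exchangeable trivariate
  normal, P(all three below median) = 1/8 + 3 asin ρ/4π; 22% scoring 3
  points gives ρ = sin(4π(0.22 − 0.125)/3) = 0.388 ≈ 0.39. The
  "worse" directions are low MiT, *high* FATiT, low pennation, so the
  signed defaults are corr(MiT, FATiT) = −0.39,
  corr(MiT, pennation) = +0.39, corr(FATiT, pennation) = −0.39.

These two constants are derived, not measured; true inter-variable
correlations beyond what the printed orthant fractions pin down are
unknown, and the remaining zeros are explicit assumptions.

`plant_outcome` adds a Bernoulli(logistic(β₀ + Σβx)) label for
parameter-recovery studies; the planted odds ratios exercised in the
tests (0.18 per cm RFMT, 1.85 female→male, 1.35 per quality-score
point) mirror the magnitudes reported for such models.

## Statistical layer

- Normality gate: Lilliefors-style Kolmogorov–Smirnov (Gaussian null
  with estimated mean/SD, table p-values) at α = 0.05; the named test
  family does not fix the variant or α, so these are fixed here.
  Zero-variance samples are non-normal by definition.
- Two groups: Student's t (equal variances) when both pass the gate,
  else Mann–Whitney U (asymptotic, tie-corrected); fully tied samples
  return p = 1 explicitly. ≥3 groups: one-way ANOVA, pairwise t-tests
  with p multiplied by the number of pairs, capped at 1.
- Correlations: Pearson or Spearman, two-sided p, error on zero
  variance.
- Logistic regression: Newton/IRLS maximum likelihood (statsmodels),
  convergence max|Δβ| < 1e-8 within 50 iterations; perfect separation
  or non-convergence raise. Wald SEs from the inverse information;
  OR = exp(β) with exp(β ± 1.96·SE) intervals — the common software
  default where the interval method is otherwise unspecified.
  Likelihood-ratio intervals would be a defensible alternative.
- Pre-registered designs: Model 1 = [age, male, RFMA, RFMT, MiT];
  Model 2 = [age, male, mass score, quality score]; outcomes sarcopenia
  or dynapenia. Sex is coded female = 0, male = 1.
- One published Model-1 dynapenia row reports an MiT odds ratio of 0.07
  with interval 0.13–0.43, which excludes its own point estimate
  (plausibly a units or transcription issue, e.g. % vs fraction
  scaling); that row is not used as a planted-recovery target anywhere
  in this package.
- No multiplicity correction beyond Bonferroni where stated;
  descriptive tables report raw p-values.

## Problem sizes and tolerances in the test suite

Simulation sizes were chosen so each check is decisive at its
tolerance: 10⁶ draws for the orthant/score distributions (Monte-Carlo
SE ≈ 0.05 pp against ±0.5 pp tolerances); 100 cohorts of 647 for the
dynapenia prevalence (±3 pp tolerance acknowledges the Gaussian
approximation to handgrip); 1,000 random histograms for the exhaustive
threshold oracle; 50 scenes for fraction recovery (±2 pp); 20 seeds for
pennation (±1°) and SFT (±0.03 cm); 200 replicates of n = 2,000 for CI
coverage (≥93% against nominal 95%); 2,000 null replicates for the
type-I error band [0.04, 0.06].

## Known limitations

- The image simulator's geometry is idealised (flat layers, exact
  ellipse, straight fascicles); detector accuracy on curved anatomy is
  untested by construction.
- The cohort generator cannot reproduce skewness, disease
  subpopulations, or the real joint distribution beyond the configured
  second moments.
- The pennation estimator assumes one dominant fascicle orientation;
  curved or fanned fascicles would bias it.
- Echogenicity class labels are surrogates; nothing here validates them
  against tissue composition.
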