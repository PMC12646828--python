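# sonomyo

Quantitative muscle-ultrasound analysis for sarcopenia research, built
around the downstream half of an AI-assisted B-mode workflow: given a
segmented rectus femoris region of interest (ROI), compute the
morphometric and echogenicity biomarkers, turn them into sex-specific
muscle mass/quality scores and EWGSOP2 classifications, and run the
cohort-level statistics. Because clinical images and patient tables of
this kind are rarely public, the package also ships first-class
synthetic generators — B-mode-like frames with planted anatomy and
cohorts with calibrated moments — so every measurement stage can be
validated against known ground truth.

Intended users are clinical-nutrition and musculoskeletal-imaging
researchers who want a tested, reproducible reference implementation of
this measurement chain, and methodologists who need a controllable
test bed for echogenicity-based biomarkers.

## What it computes

**Per image** (8-bit grayscale + binary ROI mask + cm/px calibration):

- RFMT (cm): maximal anteroposterior ROI diameter; RFMA (cm²): ROI area;
  RFMAI = RFMA/height² (cm²/m²).
- SFT (cm): skin-to-superior-aponeurosis distance on the longitudinal
  view; pennation angle (°) between fascicles and the lower aponeurosis,
  estimated from a shear-projection orientation response.
- Echogenicity biomarkers via an exact multilevel Otsu threshold search:
  two thresholds t₁ < t₂ maximising the between-class variance
  σ²_B = Σₖ ωₖ(μₖ − μ_T)² of the ROI grey-level histogram, then
  MiT = %ROI with g < t₁ (low echogenicity, muscle surrogate),
  FATiT = %ROI with t₁ ≤ g < t₂ (medium, fat surrogate),
  NMNFiT = %ROI with g ≥ t₂ (high, neither-muscle-nor-fat).
  MiT + FATiT + NMNFiT = 100 by construction; thresholds are computed
  per image, never pooled.

**Per subject**: muscle mass score (0–2; one point each for RFMA and
RFMT strictly below the sex-specific median cut-off), muscle quality
score (0–3; low MiT, high FATiT, low pennation), and EWGSOP2 categories
from handgrip strength (< 27/16 kg) and ASMI (< 7/5.5 kg/m²) —
sarcopenia = low strength + low mass, dynapenia = low strength.

**Per cohort**: normality-gated t / Mann–Whitney comparisons, one-way
ANOVA with Bonferroni post hoc tests, correlations, and two
pre-registered logistic designs with odds ratios and 95% Wald CIs
(Model 1: age, sex, RFMA, RFMT, MiT; Model 2: age, sex, mass score,
quality score), for sarcopenia and dynapenia outcomes.

## Worked example

```sh
sonomyo simulate-image --view transverse --seed 7 --out img7/
sonomyo analyze-image img7/frame.png img7/mask.png --view transverse
```

prints (provenance omitted):

```json
{
  "thresholds": [95, 175],
  "MiT": 46.6,  "FATiT": 39.45,  "NMNFiT": 13.95,
  "roi_pixels": 30891, "truncated": false,
  "rfma_cm2": 3.09, "rfmt_cm": 0.99
}
```

The planted scene (`img7/truth.json`) had class fractions
(46.55, 39.29, 14.16)%, RFMA 3.0891 cm² and RFMT 0.99 cm: the analysis
recovers the tissue fractions to well under 1 percentage point and the
morphometry exactly, because area and thickness depend only on the mask.
The thresholds 95 and 175 sit between the planted class mean intensities
(60/130/220), where a correct 3-class split must place them.

On the cohort side:

```python
import sonomyo as s

cohort = s.generate_cohort(s.CohortSpec(seed=1))        # n = 647
scored = s.score_cohort(cohort, s.published_cutoffs())
fit = s.run_model(scored, 2, "dynapenia")
print(fit.table.round(3))
```

```
                beta     se  odds_ratio  ci_low  ci_high  p_value
const          0.137  0.382       1.146   0.542    2.423    0.720
age           -0.010  0.005       0.990   0.980    1.001    0.067
male           0.521  0.168       1.683   1.211    2.340    0.002
mass_score    -0.011  0.098       0.989   0.816    1.198    0.907
quality_score  0.025  0.074       1.026   0.887    1.186    0.732
```

Each row is one predictor of the dynapenia outcome: `odds_ratio` is
exp(β) per unit of the predictor (per year, per score point; `male` is
female→male), with its 95% Wald interval. In this synthetic cohort only
sex carries a planted marginal effect on low handgrip strength (the
generator's sexes differ in handgrip), which is exactly what the fit
flags.

`sonomyo run-study --out study/ --seed 3` runs the whole chain and
writes by-sex, by-sarcopenia and by-dynapenia comparison tables, a
correlation table and all four model tables, with a provenance record.

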