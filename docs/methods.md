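# Methods

This note documents the models, conventions and parameter choices behind
`panoscape`, what the synthetic generators do and do not emulate, and the
numerical decisions a user auditing real panoramas should know about.

## Spherical geometry and the equal-area audit

A panorama is treated as a function on the unit sphere.  Equirectangular
rasters use the pixel-center convention: column *k* of width *W* has
longitude `−π + (k + 0.5)·2π/W`; row 0 is the sky side, row *r* of height
*H* has latitude `π/2 − (r + 0.5)·π/H`.  The 2:1 aspect is enforced.

Auditing happens on the Hammer projection (the standard cartographic
equations; see the module docstring), chosen because it maps the whole
sphere to a 2:1 ellipse in which equal pixel counts are equal solid
angles.  The inverse is closed-form; points with
`(x/4)² + (y/2)² > 1/2` are exterior and define the validity mask.  Two
numerical choices:

- the inverse clamps `|lat|` to `π/2 − 1e−12` so longitude stays
  determinate at the poles (visually negligible);
- forward/inverse round-trips are exact to ~1e−13 rad away from the
  poles; within ~1e−6 rad of a pole the longitude becomes
  ill-conditioned (the amplification is `1/cos(lat)`), which is
  irrelevant for areal auditing.

Resampling samples each valid output pixel at the sphere point of its
center.  Categorical rasters are restricted to nearest-neighbor sampling
— interpolation must never invent labels — while RGB rasters may use
bilinear sampling (with a wrapped column pad across the ±180° seam).
Default output width preserves the source width.  An independent oracle,
`solid_angle_proportions`, computes class shares on the equirectangular
grid with `cos(lat)` row weights; tests require the two routes to agree
within 1 % at widths ≥ 1024.

Pixel counts on the Hammer raster stand in for areas everywhere: all
three pattern metrics are area *ratios*, so physical units cancel.

## Color classification

Pixels are converted to HSV by the standard hexcone formulas
(`v = max/255`, `s = (max − min)/max`, hue in degrees; hue stored as 0
when s = 0) and classified by an ordered, first-match rule table over
(h, s, v) intervals into exactly six classes.  The shipped default:

| order | rule | class |
|---|---|---|
| 1 | v < 0.15 | black |
| 2 | s < 0.15 and v ≥ 0.80 | white |
| 3 | s < 0.15 | gray |
| 4 | h ∈ [300°, 60°) (wrapping) | red |
| 5 | h ∈ [60°, 180°) | green |
| 6 | h ∈ [180°, 300°) | blue |

Intervals are closed-open with the top of each scale included in its
final interval, which makes the partition exhaustive and boundary
behavior unambiguous (e.g. v = 0.80 with s < 0.15 is white).  These
thresholds are a *configuration*, serialized as YAML; a study with its
own calibrated cut points should encode them there.  Exhaustiveness is
checked at load time exactly, by probing one point per cell of the grid
the rule endpoints induce.  Classification is performed on the
equirectangular raster and the label raster is then reprojected; under
nearest-neighbor sampling this commutes with classifying after
reprojection (a tested invariant) and avoids classifying interpolated
colors.

No perceptual color space, white balancing or illumination correction is
applied — the classification is deliberately a raw HSV threshold model.

## Landscape-pattern metrics

Raw segmentation ids (e.g. ADE20K's 150 classes) are grouped by a
`ClassScheme` config into scene categories; ids mapped to `other` remain
a real category for the landscape-level metrics (they occupy visual
field) but are not emitted as model covariates.  Patches are maximal
connected same-category regions; connectivity defaults to 8-connected,
the FRAGSTATS convention, with 4-connected available (the 2×2
checkerboard gives DIVISION 0.75 under 4- and 0.5 under 8-connectivity —
the configuration matters and is recorded in the audit).  PLAND is
reported in percent; SHDI uses proportions in (0, 1], with empty
categories contributing 0 (the `p·ln p → 0` limit).  Metrics are
computed over the full masked ellipse, i.e. the entire sphere, not a
cropped field of view.

Implementation notes: patch labeling uses `scipy.ndimage.label`; the
test suite pins PLAND/DIVISION/SHDI to an independent flood-fill /
direct-sum oracle to 1e−12 on random rasters.  Patches do not connect
across the ±180° seam (grid convention, matching raster-based
landscape-metric programs).

## Statistical models

*Linear family* (nine continuous indicators: six EEG performance metrics
in [0,1], SCR count, summed SCR amplitude, mean heart rate): OLS with
the outcome and the five continuous covariates of one layer z-scored
(sample SD, ddof = 1) and the dummies — large/small street scale (medium
reference) and gender (male = 1) — entered raw.  Fully standardizing
dummies would make their coefficients uninterpretable; the standardized
slopes of the continuous covariates are comparable effect sizes.
Per-coefficient two-sided t-tests; overall significance from the F-test.

*Multinomial family* (three ordinal 1–3 ratings): maximum-likelihood
multinomial logit, level 1 reference, Newton iterations from zero
coefficients (max 200).  Coefficients are reported on the raw covariate
scale by default — the magnitudes then directly reflect per-unit
covariate changes — with a `standardize_x` toggle.  Per-coefficient Wald
tests; overall significance from the likelihood-ratio test against the
intercept-only model, whose fitted probabilities equal the observed
level frequencies (a tested identity).  Non-convergence (e.g. under
separation) raises a warning flagging possible diverging coefficients.

Records missing an outcome are dropped per model, not globally, so each
indicator family keeps its own valid N.  Exact collinearity raises an
error naming the collinear set; the pipeline enables a pruning mode
(greedy, earlier columns win) because very small scene sets cannot
identify all eight predictors.  No multiple-testing correction is
applied, matching the three-level star convention (* < 0.1, ** < 0.05,
*** < 0.01) of this literature.

**Caveat:** repeated scenes within a participant are pooled, not
modeled; there is no participant random effect.  This mirrors the
analysis design the package reproduces, but p-values for covariates
would be anticonservative if real responses carried strong
participant-level correlation.  A mixed-effects extension is explicitly
out of scope.

*Correlations*: Pearson between continuous indicators, Spearman whenever
an ordinal rating is involved; pairwise deletion (cells with < 3
complete pairs are reported missing).  Whether to use pairwise or
listwise deletion across indicator families with different valid N is a
genuinely open choice; pairwise is the default because it uses all
information each cell has.

## Synthetic data

`generate_scene` tiles the sphere with a sky band, a road band, a
building facade remainder, and plant disks scattered over the facade;
band areas are closed-form (`(sin φ₂ − sin φ₁)/2`), disk coverage is
measured by cosine-weighted counting, and the returned truth is exact
for the rendered raster.  Prototype colors classify to green (plant),
blue (sky), gray (road) and red (facade) with jitter that preserves the
class: achromatic categories receive only a shared luminance offset
(saturation stays 0), chromatic ones a bounded per-channel offset.
Scene-feature distributions emulate a real street corpus: sky share
N(18.8 %, 7.2 %), road N(40.1 %, 3.6 %), plant target N(16.6 %, 10.1 %),
street scales 44/33/23 % small/medium/large.  What the generator does
*not* emulate: real segmentation noise, objects spanning category
boundaries, perspective structure, shadows and illumination gradients —
so passing closure tests validates the measurement chain, not the
behavior of any segmentation model on real imagery.

`generate_cohort` mirrors the study footprint: 26 participants, four
scene groups of 12, gender Bernoulli(0.5) per participant.  Generative
laws are declared conventions chosen to respect each indicator's range,
not inferences about real data:

- EEG metrics: logistic squash of a Gaussian linear predictor (keeps
  values strictly inside (0, 1); intercepts/noise chosen so marginal
  means and SDs resemble reported descriptives, e.g. engagement
  ≈ 0.69 ± 0.09);
- SCR count: Poisson with log link, baseline mean 8.12;
- summed SCR amplitude: gamma (shape 1.2) with mean 0.23 mμS per SCR,
  tied to the drawn count;
- heart rate: identity-link Gaussian, 76.6 ± 10 bpm, floored at 1;
- ratings: multinomial draws from logits with level 1 as reference.

Covariate effects are specified on the z-scored covariate scale at the
record level, so recovery runs can compare fitted coefficients directly
against the generating values.  Default effects encode the headline
exposure pattern (diversity raises comfort/vitality, fragmentation
lowers them; gender shifts excitement/interest/arousal/heart rate) at
magnitudes that are weak at n ≈ 310 and clearly recoverable at
n = 2000.  Per-family missingness defaults mirror the valid-N pattern
such studies report (EEG 208/312, SCR 213/312, HR and ratings 310/312);
calibration and recovery configurations turn missingness off.

Monte-Carlo replicate seeds are derived with
`numpy.random.SeedSequence.spawn` (`simulate.spawn_seeds`) rather than
sequential integers: spawned streams are the recommended way to obtain
independent replicates, and sequential seeding showed measurable
between-block variance inflation in calibration experiments.

## Problem sizes used in the checks

Generator/auditor closure is exercised on 8 sampled scenes at width
1024 (1 % tolerance); the sky-band audit uses width 2048 in the
acceptance script; metric-oracle equivalence uses 100 random 16×16
rasters at 1e−12; null calibration uses 1000 replicate cohorts of
26 × 12 records (KS uniformity on 500); parameter recovery uses one
cohort of 2000 records (200 participants × 10 scenes) with every
coefficient required within 3 estimated SE of its generating value; the
determinism check reruns a 5-scene × 6-participant pipeline and compares
file hashes.

## Known limitations

- Default HSV thresholds and the ADE20K grouping ship as editable
  configs, not calibrated ground truth.
- Semantic segmentation itself is upstream: the package consumes label
  rasters and cannot correct their errors.
- No participant-level random effects (see above); no ordinal
  proportional-odds alternative to the multinomial model.
- Landscape metrics beyond PLAND/DIVISION/SHDI (edge density, contagion,
  fractal dimension) and patch-level exports are out of scope.
- Scene rendering is schematic by design; photorealism and time-series
  physiological waveform synthesis are non-goals.
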