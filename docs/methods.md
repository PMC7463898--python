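# Methods

`rectomics` implements a radiomic analysis of the rectal environment on
post-chemoradiation T2-weighted MRI: texture and shape descriptors of the
rectal wall and lumen are extracted per patient, pruned and ranked, and
used to discriminate pathologic tumour down-staging (ypT0–2) from
non-regressed disease (ypT3–4) with a quadratic discriminant model,
followed by robustness statistics and unsupervised cluster evaluation.
Because no patient images are distributed with the package, every stage
is exercised and validated on synthetic phantom cohorts whose geometry
and statistics mimic the clinical data structure.

## Data model

A `StudyCase` holds one 3D T2w volume (array indexed `[x, y, z]`, section
index on the third axis, physical spacing in mm from the image header)
and three aligned binary masks: the entire rectal wall `R^E`, the lumen
`R^L`, and the primary treated tumour sub-region of the wall `R^P`, plus
the pathologic-stage label and acquisition metadata (institution, field
strength, sex, cohort). All volumes are linearly resampled (masks:
nearest-neighbour) to 0.781 × 0.781 × 4.0 mm, the most common acquisition
resolution in the discovery cohort; edge voxels are nearest-neighbour
extrapolated so constant volumes stay constant under resampling.

Texture is computed on a sub-volume of `R^P` consisting of the largest
annotated 2D section plus its two neighbours (3 consecutive sections).
Boundary and tie rules are fixed deterministically: ties on area break
toward the lower section index, and a maximal section at the edge of the
annotated span shifts the 3-section window inward. Fewer than 3 annotated
sections degrade gracefully to the available sections with a warning.

## Texture bank (191 maps → 764 features)

Per 2D section (section thickness ≈ 5× the in-plane resolution, so 2D
neighbourhoods are the natural support):

| family    | maps | construction |
|-----------|------|--------------|
| histogram | 21   | local mean, median, std, range, min, max, IQR in windows 3/5/7 |
| gradient  | 10   | dx, dy, magnitude, orientation, Sobel x/y/diag/anti-diag, Laplacian, Kirsch-compass max |
| haralick  | 65   | 13 co-occurrence statistics × windows 3/5/7/9/11 |
| gabor     | 35   | 5 wavelengths × 6 orientations (π/8 … 3π/4) + per-wavelength orientation maximum |
| laws      | 34   | all 3×3 (L3/E3/S3) and 5×5 (L5/E5/S5/W5/R5) separable kernels |
| collage   | 26   | 13 co-occurrence statistics of the dominant gradient-orientation image × windows 3/5 |

Each map is summarized over the ROI by mean, variance, skewness and
excess kurtosis (constant maps score 0 skew/kurtosis by convention),
giving 764 features; the median is available as an optional fifth
statistic but excluded from the default count.

Numerical choices:

- **Quantization.** Haralick levels use 64 equal-width bins over the
  ROI min–max of the 3-section sub-volume; a constant ROI maps to level 1.
  Co-occurrences pool the 4 in-plane unit offsets, are symmetrized and
  normalized, and only count pixel pairs that both lie inside the ROI and
  the window — so wall statistics never leak lumen or background
  intensities. Degenerate windows (single grey level, or an isolated ROI
  pixel) use the limiting conventions entropy = 0, correlation = 0,
  energy = 1. Statistics use 1-based levels, so a uniform window at level
  g has sum-average 2g.
- **Border handling.** Convolution-type families run on a crop of the
  section in which out-of-ROI pixels are replaced by their nearest in-ROI
  value, with reflective padding at the crop border; this keeps filter
  responses at the wall boundary driven by wall tissue only.
- **Gabor.** The wavelength list (0.765, 0.128, 1.786, 2.296, 2.806 —
  the second value is kept verbatim from the source protocol although it
  breaks the ascending order, and is configurable) maps index-wise to
  kernel windows 3/5/7/9/11; σ = ws/5, unit aspect ratio, and the real
  kernel is re-centred to zero mean so responses ignore constant offsets.
  The 35-map count is reached by adding the per-wavelength maximum over
  orientations to the 30 (λ, θ) responses.
- **CoLlAGe.** The dominant orientation per pixel is the principal
  direction of the window-averaged (uncentred) gradient structure tensor,
  mapped to [0, π) and quantized to 8 bins (zero-gradient neighbourhoods
  take bin 0); co-occurrence statistics of that orientation image reuse
  the Haralick machinery. Because the structure tensor is window-averaged,
  neighbouring orientations are correlated and the per-voxel entropy
  stays below the log₂(8²) matrix bound even for random images.
- The sliding-window co-occurrence kernel is compiled with numba; a pure
  Python brute-force oracle in the test suite checks it exactly.

## Shape morphometry (198 features)

For each of `R^E` and `R^L`, 25 3D descriptors are computed from
physical-space voxel moments and the 3D convex hull: projection extents
along the principal axes, equivalent-ellipsoid diameters (2√(5λᵢ)),
equivalent-sphere radius/surface, eccentricity, elongation, flatness,
orientation angles, principal moments, compactness (volume over the
volume of the moment-equivalent sphere — exactly 1 for a ball, no
surface-area estimate needed), roundness (volume over the volume of a
sphere with the hull's surface area), volume, extent, solidity, convex
and bounding-box volume. A small diagonal correction (spacing²/12) makes
the voxel moments match their continuous counterparts. Four
inter-structure descriptors take wall-minus-lumen differences of
equivalent-sphere radius/perimeter and major/minor axis length.

Per section, 18 2D descriptors (axis lengths, convexity, perimeters,
eccentricity, compactness, solidity, …) are computed with scikit-image
region properties plus convex hulls in physical coordinates; perimeters
use the Crofton estimator. The per-section series of each descriptor is
differenced between consecutive (non-empty) sections and summarized by
mean, variance, skewness and excess kurtosis: 72 slice-series features
per structure, quantifying how wall/lumen morphology fluctuates along the
rectum. Summarizing the raw (undifferenced) series is available behind a
config flag. Totals: 25·2 + 4 + 72·2 = 198.

The 3D descriptor set is a documented reconstruction: the published
12-item descriptor table reaches 25 per structure only under a per-axis
expansion, which is fixed here as the default; likewise the four
"diameter-based" inter-structure differences are a reconstruction.

## Feature table and normalization

Texture features carry a `T.` prefix, shape features `S.` (962 columns,
sorted for determinism). Each feature is normalized by subtracting its
mean and dividing by its mean absolute deviation about the mean (the MAD
here is mean-based, matching the pairing with the mean, not
median-based). Parameters are fit on the discovery cohort only and
frozen for the validation cohort — joint normalization would leak
hold-out information. Zero-MAD (constant) features are dropped with a
logged warning.

## Feature selection

Stage 1 prunes each block: keep features with two-sided Wilcoxon rank-sum
p ≤ 0.05 between stage groups (the threshold is a package choice; the
source protocol leaves it unstated), then scan survivors in ascending-p
order, dropping any feature with |Pearson r| > 0.6 to an already-kept
feature — the most class-associated member of each correlated cluster
survives. The rank-sum test uses the exact null distribution for combined
n ≤ 20 without ties and the tie-corrected normal approximation otherwise;
a vectorized approximation handles whole-table screening. Inside
cross-validation folds the significance cut-off (never the correlation
rule) is relaxed just enough to keep at least k candidates.

Stage 2 ranks survivors by greedy mRMR with the mutual-information
difference criterion I(f; label) − mean I(f; selected), features
discretized by equal-frequency 10-bin coding. The combined block `F^T+S`
concatenates the pruned texture and shape survivors before mRMR. Note a
structural coupling: features sharing the class signal are themselves
correlated (r ≈ d²/4 / (1 + d²/4) for a common shift d), so strong
common effects can eliminate each other at the 0.6 pruning threshold —
visible in the ground-truth recovery tests.

## Modeling and evaluation

Discovery-cohort model selection uses randomized stratified 3-fold CV:
two folds drive the entire two-stage selection and the classifier fit,
the third is scored; 50 random repeats by default. Features are ranked by
selection frequency across all folds (ties by summed mRMR relevance,
then name), and the top k (4 by default, 4–6 supported) train the final
model. Re-running selection inside every fold is what keeps null-data CV
AUC unbiased near 0.5; the package ships an explicit contrast experiment
showing the inflation when selection is done once on the full table.

The QDA classifier is implemented directly as class-conditional Gaussians
with per-class covariance and equal priors; class covariances whose
smallest eigenvalue falls below 1e-6 receive a ridge of that size (the
scikit-learn QDA serves as an independent oracle in tests but refuses
small-class fits the ridge handles). The random-forest alternative uses
500 trees with √p features per split. The decision threshold maximizes
Youden's J on discovery scores (the "optimized threshold"; the rule is a
package choice). The positive class is ypT0-2 throughout. Hold-out
metrics: rank-based AUC, confusion counts at the frozen threshold,
accuracy, sensitivity, specificity and MCC (0 by convention when a
marginal is empty), with per-institution and per-sex breakdowns; strata
containing one class report AUC as missing.

## Robustness

Top-ranked features (6 texture + 6 shape) are compared between 1.5 T and
3.0 T scans by Wilcoxon rank-sum with a Bonferroni-corrected threshold
0.05/12 → 0.004 (reported to 3 decimals). Annotation sensitivity
recomputes features under a second, deterministically jittered set of
wall/lumen masks for a 20-case subset (10 per cohort), comparing rater
pairs per feature by rank-sum p (the unpaired test, as specified, not
the signed-rank variant) and ICC(2,1) — two-way random effects, absolute
agreement, single rater, via pingouin — plus per-structure Dice overlap.
ICC is reported missing when between-subject variance vanishes.

## Embedding and consensus clustering

Each feature set is embedded into 3D by t-SNE (random initialization,
Euclidean metric, 1000 iterations, perplexity 30 auto-reduced to
(n−1)/3 for small cohorts, with a log message). One numerical deviation
from library defaults: scikit-learn's automatic learning rate is floored
at 50, which overshoots badly for cohort-sized n and leaves the
optimization visibly unconverged (duplicated rows land far apart); the
floor is lowered to 10, restoring KL ≈ 0.05 on separable toy data.

Consensus clustering runs 1000 rounds of average-linkage hierarchical
clustering on random 80% patient subsamples, distance 1 − Pearson
correlation between embedding 3-vectors, cut at k = 2; the consensus
matrix records co-assignment frequency among co-sampled rounds (pairs
never co-sampled are reported missing, not 0), and the final assignment
cuts average linkage on 1 − consensus at k = 2. Pearson distance between
3-vectors is translation-degenerate (it sees only the profile shape of
the coordinates); it is retained as specified but rows with constant
coordinates raise an error. Cluster-vs-label accuracy uses the
cluster-to-label matching that maximizes overall agreement, with
per-class fractions.

## Phantom generator

The generator is first-class, tested code that defines the study
conditions. Each case is a tube: per-section elliptical lumen inside an
annular wall, with centre, lumen radius, wall thickness, eccentricity and
orientation evolving along z as stationary AR(1) profiles (ρ ≈ 0.85–0.9),
over 20–60 sections of an 80 × 80 grid at 0.781 × 0.781 × 4.0 mm.
Intensities are arbitrary units (the pipeline normalizes features, not
intensities): wall ≈ 100 with a class-scaled sinusoidal ripple along the
in-plane x axis (wavelength 6 mm) to excite directional gradient
features, lumen ≈ 25, background ≈ 50, mild in-plane Gaussian blur for
partial-volume softening, additive Gaussian noise (sd 4). `R^P` is a
contiguous 4–9-section span of the wall.

Class conditions (chosen once as plausible disease effects; the source
reports no effect sizes, so these are not calibrated to any published
p-value): wall thickness mean 4.0 vs 6.5 mm (sd 0.8 vs 1.6 — thicker and
more variable walls for ypT3-4), lumen eccentricity 0.45 vs 0.65,
ripple amplitude 6 vs 12 (diminished gradient expression in down-staged
cases). Cohorts reproduce the study composition: 52 discovery cases
(22 ypT0-2) from one institution, nearly all 3 T; 42 validation cases
(16 ypT0-2) split over two institutions with a 1.5/3 T mix and an
all-male third-institution subset. Identical (parameters, seed)
reproduce cases byte-for-byte.

What the phantoms do *not* emulate: anatomy (mesorectum, haustra),
scanner physics (bias fields, motion, coil profiles), inter-institution
intensity distribution shifts, or annotation ambiguity. Passing tests
therefore demonstrate that the pipeline recovers effects it is pointed
at and stays honest under the null — not that the published patient-level
AUCs are reproducible; those depend on undistributed clinical data.
Under the default class effects the phantom classes separate almost
perfectly (hold-out AUC ≈ 1), which is stronger than any clinical
signal; the null and injected-effect experiments are the calibrated
evidence.

## Validation experiments and problem sizes

- **Null calibration:** 10 master seeds × (52+42) null phantoms
  (identical class parameters); hold-out AUC must stay in [0.35, 0.65]
  on average and the Wilcoxon survivor fraction near the 0.05 test level.
- **Parameter recovery:** the same null tables with 4 ground-truth
  features (2 directional-gradient texture, 2 wall-shape) shifted by
  d = 1.5 pooled SDs; the injected features must occupy the top-4
  selection-frequency ranks in ≥ 8/10 seeds and restore hold-out
  AUC ≥ 0.85. CV inside these multi-seed experiments uses 10 repeats
  (50 in single-run analyses) and selects k = 6 features per fold, the
  top of the supported 4–6 range: because the injected features share
  the class signal they are mutually correlated, and the mRMR difference
  criterion penalizes them for it while an independent noise feature
  pays no such penalty — at k = 4 a stable interloper can displace the
  weakest injected feature from the per-fold selection, whereas at k = 6
  all four are selected per fold and their frequencies dominate the
  ranking.
- **Demo pipeline:** a 60-phantom configuration exercises every stage
  end-to-end and is byte-reproducible under a fixed seed.

## Known limitations

- Haralick/CoLlAGe windows at the thin ends of the wall ring contain few
  in-ROI pairs; statistics there rest on small co-occurrence counts.
- Plug-in mutual information is biased upward at these sample sizes
  (bias ≈ (bins−1)²/2n nats for feature–feature MI); the bias largely
  cancels between candidates in the mRMR difference criterion but can
  occasionally swap a weak true feature for noise.
- The 2:1 section-thickness anisotropy means 3D moments are dominated by
  the z extent for long structures; descriptors are reported in physical
  mm, but no anisotropy correction beyond the spacing itself is applied.
- DICOM reading supports axis-aligned series with uniform slice spacing;
  oblique acquisitions are out of scope.
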