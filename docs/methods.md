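# Methods

`longiperf` implements a longitudinal multiparametric-MRI radiomics
pipeline for surveillance of treated high-grade glioma, where the clinical
question at each follow-up is three-way: progressive disease (PD),
pseudoprogression (PsP — treatment-related change that mimics progression),
or stable disease (SD). This note documents the model, the synthetic study
conditions, the numerical choices, and what the package's tests do and do
not establish.

## Pipeline

Each subject contributes one to three imaging time points, each a bundle of
six co-registered 3-D maps — T1, post-contrast T1 (T1Gad), T2, FLAIR, and
the DSC-perfusion maps rCBV and rCBF — plus a lesion mask and a deep-grey
(basal-ganglia surrogate) reference mask on a common grid. The stages are:

1. **Normalisation.** Structural maps are log-transformed and robustly
   z-normalised within the brain mask (subtract median, divide by
   1.4826·MAD). Perfusion maps are z-scored against the reference region:
   `z(v) = (v − mean_ref) / sd_ref`, yielding the ZrBV and ZrBF maps. The
   reference region therefore sits at mean 0, SD 1 exactly; everything
   downstream works on these unitless maps.
2. **Subtraction imaging.** For multi-time-point subjects, voxelwise
   differences of the normalised maps are formed for the pairs (2−1),
   (3−2), (3−1). The feature region for a difference image is the union of
   the two lesion masks, so both growth and shrinkage contribute voxels.
3. **Feature extraction.** Over each region (per-time-point lesion, and
   each subtraction union mask), per map: 11 distribution features (mean,
   SD, min, max, quartiles, skewness, excess kurtosis, energy = mean
   square, 64-bin natural-log entropy) and 7 grey-level co-occurrence
   (Haralick) features (contrast, dissimilarity, homogeneity, ASM, entropy,
   correlation, sum average). Names are `<region>_<map>_<feature>`, e.g.
   `Diff21_ZrBF_FirstQuartile`. With 6 maps and 18 features the count is
   pure configuration arithmetic: 108 per region, 324 for a two-time-point
   subject (TP1, TP2, Diff21); it is logged, never hard-coded.
4. **Classification.** Two independent one-vs-rest binary stages — "SD vs
   rest" and "PD vs rest" — each a pipeline of per-feature standardisation,
   L1-penalised logistic feature selection, and an RBF-kernel SVM with
   balanced class weights. Stage outputs combine by precedence: PD if the
   PD stage fires, else SD if the SD stage fires, else PsP; a conflict
   resolves to PD, because a missed progression is the costlier clinical
   error.
5. **Evaluation.** Repeated stratified two-fold cross-validation (default
   250 iterations; desk-scale runs use fewer, see below). Every iteration
   redraws the split and refits the whole nested pipeline per training
   fold; held-out predictions pool into that iteration's error rate. Both
   the median and the mean error across iterations are reported, since the
   error distribution is skewed. Per-subject modal held-out predictions
   provide the single label per case used for sensitivity/specificity
   (PD positive vs PsP+SD) and for the McNemar comparison against rater
   labels.

## GLCM construction

Texture uses 3-D co-occurrence over the 13 unique voxel offsets at
distance 1, symmetrised, normalised to sum 1 per direction before
averaging (so directions with fewer valid pairs are not down-weighted).
Both pair members must lie inside the mask. Grey levels are 32 equal-width
bins between the masked region's own min and max — z-scored and difference
maps have no global intensity scale, so region-local quantisation is the
defensible default. All of this is configurable via `GLCMConfig`.
Degenerate regions resolve to fixed conventions (constant region: SD,
skewness, kurtosis and entropies 0; GLCM correlation 1) so feature matrices
are always complete; the scale-dependence of quantised texture features
(they are not invariant under intensity scaling, unlike the distribution
shape statistics) is inherent and documented in the tests.

## LASSO selection and SVM tuning

Selection fits an L1-penalised logistic path on standardised features. The
penalty grid spans the analytically smallest all-zero lambda down to 1e−3
of it (12 points); lambda is chosen by stratified inner CV (3 folds,
reduced automatically for very small classes) on binomial deviance with
the one-standard-error rule. An empty selection falls back to the largest
lambda keeping at least one coefficient, and finally to the single
strongest univariate feature, so a stage can always be trained. The SVM
grid is deliberately small — C ∈ {0.1, 1, 10, 100}, gamma ∈
{0.1, 1, 10}/n_selected — tuned by inner stratified CV accuracy. All inner
choices are functions of the training fold only; a unit test asserts the
held-out fold never reaches `fit`.

## Synthetic study conditions

No patient data ship with the package; the generator emulates the
statistical structure the analysis needs, as a pure function of
(config, seed):

- **Anatomy.** An ellipsoidal brain on a 36³ grid at 2 mm spacing; a
  two-compartment piecewise-constant background (white matter plus a fixed
  deep-grey ellipsoid pair that doubles as the reference region) softened
  by a 1-voxel Gaussian blur; a smooth Gaussian random field (5% amplitude,
  2-voxel correlation) supplies within-tissue variability — and hence a
  non-zero reference SD.
- **Lesion.** An ellipsoid (radius ~N(12, 3²) mm, class-dependent growth
  per time point) at a fixed location. Lesion voxels carry a
  mean-normalised lognormal texture field (class-dependent SD: PD 0.35,
  PsP 0.20, SD 0.15, smoothed at 0.8 voxel); mean-normalisation makes the
  lesion-mean contract exact in-sample at zero noise.
- **Class contrasts (defaults).** Lesion rCBV/rCBF z-mean: PD 2.0 (slope
  +0.8 per time point), PsP 0.5 (−0.4), SD 0.3 (0); T1Gad enhancement:
  PD 1.6 (+0.3), PsP 1.5 (+0.3 then −0.4 — the rise-then-fall course that
  makes longitudinal features informative), SD 1.0. The rCBF trajectory
  reuses the rCBV profile. Signal is deliberately split across modalities:
  perfusion separates PD from the rest, enhancement separates PsP from SD,
  so neither modality alone suffices for the 3-class problem.
- **Realism knobs.** Between-subject jitter (SD 0.25 z-units on perfusion,
  0.08 a.u. on enhancement), additive Gaussian noise sigma 0.05 a.u.
  (Rician available, since magnitude-MR noise is Rician; Gaussian default
  for analytic tractability). Rater labels corrupt the truth per class
  (PD 0.20, PsP 0.35, SD 0.20 error), putting simulated-rater accuracy
  near 0.75–0.80, the range reported for radiologist reads of this
  problem.
- **Trajectory variant.** `trajectory_signal_profiles()` makes PD and PsP
  identical at the first time point (z 1.5, enhancement 1.5, equal texture)
  and opposite in slope — the conditions under which single-time-point
  features cannot separate them and the longitudinal gain is measurable.

What the generator does **not** model: realistic anatomy, bias fields,
motion, registration error, skull stripping, or DSC time-series signal
formation (the generator emits rCBV/rCBF maps directly). Passing tests
therefore demonstrate that the pipeline recovers the structure it assumes,
not that it would perform at any particular level on clinical data.

## Evaluation details and null behaviour

- An iteration's error is the pooled held-out misclassification fraction
  over both folds; pooled confusion counts reproduce the mean error
  exactly.
- The McNemar test uses the exact two-sided binomial tail below 25
  discordant pairs and the continuity-corrected chi-square above. The
  exact p matches full enumeration of all 2^(b+c) discordance outcomes
  (tested for b+c ≤ 12) and statsmodels' exact implementation.
- The permutation null control uses a class-balanced cohort: with balanced
  class weights in the SVM, chance accuracy equals the majority-class rate
  only when classes are balanced, which makes that the cohort where
  "accuracy ≈ majority rate under permutation" is the correct null
  statement.
- Exact McNemar p-values are discrete and conservative, so under the null
  they are sub-uniform rather than uniform; the null-control test asserts
  no over-rejection at any level instead of literal uniformity.

## Problem sizes

Desk-scale defaults used by the test suite and `scripts/acceptance.py`,
chosen as the package's standard demonstration conditions: the default
cohort is 60 subjects (30 PD / 15 PsP / 15 SD) with two time points and
50 CV iterations; replicate-cohort ordering experiments use ten cohorts of
19 subjects (8 / 5 / 6 — a typical multi-time-point surveillance arm) with
8–12 CV iterations each. The CV iteration default of 250 remains available
through `CVConfig`.

## Known limitations

- The exact clinical feature inventory this class of study uses is not
  standardised; the 18-feature set here is one defensible instantiation,
  and counts depend on it.
- Subtraction features are computed as features-of-difference-images; the
  alternative (differences-of-features) is not implemented.
- PsP remains the hardest class under the stepwise rule (it is predicted
  only when both stages decline), which mirrors its clinical ambiguity but
  means 3-class error is dominated by PsP/SD confusion.
- No probability calibration, ROC analysis, or confidence intervals on the
  diagnostic metrics.
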