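# Methods

`rectomics` re-implements, as a tested pipeline over synthetic cohorts, an
MRI-radiomics procedure for predicting pathological response of locally
advanced rectal cancer (LARC) to neoadjuvant chemoradiotherapy, including the
comparison between manually drawn and automatically generated tumour masks.
This note records the model, the numerical conventions, the synthetic-data
design, and the choices made where the procedure admitted more than one
reading.

## Reference standard and splits

Each case carries a Mandard tumour regression grade (TRG, 1–5); TRG 1–2 is a
*responder*, TRG ≥ 3 a *nonresponder* (`imaging.label_from_trg`). Cases from
centres A and B form the *construction set*, split 70/30 (stratified by
label) into construction-train and construction-test; centre C is an
untouched *external validation set*. A split-tag guard in
`evaluate.validate` refuses to score construction rows, and normalization
parameters are fitted on construction rows only.

## Feature extraction

Per case and mask provenance the extractor produces exactly 157 features:
ROI volume from the T2w mask, four first-order statistics of the raw ADC
values (mean, SD with n−1, moment skewness m₃/m₂^1.5, kurtosis m₄/m₂²,
returned as 0/0 for a numerically constant sample), and per modality 76
texture features: 25 co-occurrence (GLCM; the 24 reference features plus sum
variance), 16 run length (GLRLM), 16 size zone (GLSZM), 5 neighbourhood
grey-tone difference (NGTDM) and 14 dependence (GLDM) features. The
catalogue in `rectomics.catalogue` is the single source of truth for names
and counts (77 T2w-derived + 80 ADC-derived).

Pipeline per modality:

1. **Re-segmentation** — the ROI is restricted to voxels inside the closed
   [P1, P99] intensity band of the in-mask distribution. Percentiles use
   linear interpolation between order statistics; ties at the bounds are
   retained, so a constant ROI is unchanged. Applied independently per
   modality. No denoising filter and no global intensity normalization are
   applied anywhere; ADC first-order statistics use raw values.
2. **Discretization** — fixed bin count N = 64 between the re-segmented ROI
   minimum and maximum: level(x) = 1 + ⌊N(x − min)/(max − min)⌋, clamped to
   N at x = max; a constant ROI maps to level 1. This makes every texture
   feature invariant to positive affine intensity transforms (tested).
3. **2.5D extraction** — texture matrices are built per axial slice, strictly
   in plane, at Chebyshev distance 1. GLCM and GLRLM use the four in-plane
   directions (0°, 45°, 90°, 135°); GLSZM zones are 8-connected; NGTDM and
   GLDM use the 8-neighbourhood. Features are averaged over directions
   within a slice, then (unweighted) over slices, which makes the aggregated
   directional features invariant to 90° rotations and axis flips (tested).
   Slices with fewer than 2 ROI pixels are dropped.

Conventions for degenerate inputs, chosen so no feature is ever NaN:

* runs, zones and dependences never cross ROI boundaries; out-of-ROI
  neighbours are ignored, not read as level 0;
* GLCM is symmetrized by adding the transpose; matrices are normalized to
  unit mass; Ng in Idmn/Idn (and Ngp in NGTDM) counts levels actually
  present;
* GLCM correlation at zero grey-level variance is 0, MCC of a single-level
  matrix is 1, NGTDM coarseness of a flat ROI is capped at 10⁶;
* GLDM dependence size is 1 + (number of 8-neighbours within α = 0 level
  difference), counting the centre voxel, so size-weighted denominators are
  positive;
* a direction with no pixel pairs on a slice is skipped in that slice's
  direction average; a slice supporting no valid matrix for a family is
  skipped in that family's slice average.

The brute-force oracle in `tests/oracles.py` transcribes every formula as
literal loops; the acceptance suite checks agreement on 200 random slices at
1e-10 relative tolerance.

## Feature selection

Features are min–max scaled with minima/maxima from the construction set;
validation rows are transformed with the same parameters and deliberately
not clipped. Three selectors operate on normalized construction rows:

* **Stability-resampled AUC ranking.** Per feature the tie-corrected
  Mann–Whitney AUC, folded to max(a, 1−a) so discrimination in either
  direction scores alike. Correlation pruning repeatedly removes the
  lower-AUC member of the most-correlated pair until no |Pearson r| ≥ 0.85
  remains (AUC ties drop the lexicographically later name). The procedure is
  repeated on 100 label-stratified 70% resamples; features surviving ≥ 70
  resamples are kept, ordered by full-construction-set AUC. Stratification
  is a deliberate strengthening of plain resampling: it prevents single-class
  resamples at small n.
* **Affinity propagation** over the feature-similarity matrix (negative
  squared Euclidean distance between standardized columns), preference =
  median off-diagonal similarity, damping 0.7, ≤ 500 sweeps, converged when
  the exemplar set is stable for 30 sweeps. The message-passing updates are
  implemented in-package and cross-checked against scikit-learn's
  implementation in the tests. Exactly identical columns are collapsed
  before message passing, and the exemplar criterion is boundary-inclusive
  (diag(R)+diag(A) ≥ 0), which fixes the two degenerate cases (all features
  identical → one exemplar; two equidistant features → both).
* **mRMR (MIQ).** Greedy ranking by relevance/mean-redundancy quotient with
  plug-in mutual information after equal-frequency binning into 4 bins.

All three subset sizes use the same *overfitting point* rule on a
linear-SVM (C = 1) accuracy curve over top-k subsets: mean sub-training
accuracy from stratified 6-fold CV on construction-train versus accuracy on
construction-test; the chosen size is the largest k with non-decreasing test
accuracy up to k followed by rising train and strictly falling test accuracy
at k+1, else the smallest k maximizing test accuracy. Candidate sizes are
capped at the construction-train sample count — beyond that the fit is
degenerate at these cohort sizes.

## Classifiers

Four families with responder as positive class, all seed-reproducible:

* SVM: kernels linear / polynomial (order 3, coef0 1) / Gaussian (kernel
  scale by the median pairwise-distance heuristic), box constraint over
  {1, 2, 5, 8, 10, 15, 20, 30, 40, 50} covering the range 1–50; scores are
  Platt-calibrated probabilities so thresholds and AUCs are comparable
  across families.
* Gaussian naive Bayes, no tuning (zero-variance features get a floored
  variance with a warning).
* Ensembles with 100 learners: bagged random forest (√p features per split,
  bootstrap) and AdaBoost on depth-1 stumps with learning rate 1.
* Logistic regression: plain GLM, and forward–backward stepwise selection
  from the intercept-only model using the deviance-based F-approximation of
  single-term tests, adding the smallest p < p-Enter ∈ {0.05, 0.1} and
  removing any p > p-Remove ∈ {0.2, 0.3} (p-Enter < p-Remove is enforced).
  (Quasi-)separated fits fall back to a ridge-regularized fit (λ = 1e-6)
  with a warning.

Grid search maximizes mean stratified 6-fold CV accuracy on the construction
set (hard-label fits in the CV loop; the final refit carries calibrated
probabilities); ties go to the simpler candidate (linear < polynomial <
Gaussian, smaller C, fewer terms). A family whose best CV accuracy does not
exceed 0.5 is flagged ineligible. Fold counts are clamped to the smaller
class where cohorts are tiny.

## Model selection, validation, statistics

The construction-set performance of each (selector × family) candidate is
computed from out-of-fold predictions of repeated (2×) stratified 6-fold CV
with averaged scores — a deliberately cross-validated estimate; the repeat
stabilises the AUC at n ≈ 20. The best model maximizes construction accuracy
with PPV then fewer-features tie-breaks, after excluding any candidate whose
construction AUC ≥ 0.99 as clear overfitting; if everything is excluded that
is an error, not a silent fallback.

Metrics are ACC/SE/SP/NPV/PPV with responder positive; zero-denominator
metrics are reported as undefined, never 0. Printed percentages round to the
nearest integer, half away from zero — the rule under which the published
rate/percentage pairs (e.g. 10/16 → 63%) are mutually consistent.
Proportion CIs are Clopper–Pearson; AUC (unfolded, positive-class
orientation) gets a seeded class-stratified bootstrap CI (2000 replicates).
The CI method for the published tables is not stated, so printed CIs are not
reproduction targets. Group contrasts (tumour volume and DSC of correct vs
misclassified cases) use the two-sided Mann–Whitney U test, exact by
enumeration for group sizes ≤ 8 without ties, otherwise the
normal approximation with tie and continuity corrections. Paired model
comparison reports both the two-proportion z-test per metric (the
study-style comparison) and McNemar's exact test on discordant pairs, which
is the statistically appropriate primary test for paired predictions.

Hybrid validation applies a frozen model (and its normalization) to the
validation feature rows of the *other* mask provenance. In the automatic
track, construction cases whose automatic mask overlaps the manual reference
at Dice < 0.20 are excluded from training as segmentation failures;
validation cases are never excluded.

## Synthetic data

No imaging data were deposited with the study, so the cohort generator is a
first-class module that emulates the statistical structure the analysis
assumes — not MRI physics. Per case: an ellipsoidal tumour (in-plane radius
6–10 mm, mild anisotropy) in a background volume with per-centre voxel
spacing (A 0.43×0.43×4 mm, B 0.47×0.47×3.5 mm, C 0.8×0.8×3 mm; native ADC
grids are coarser and resampled onto the T2w grid at ingestion, as in the
pipeline's own ingestion path). TRG is sampled within class with the
published marginals (16:26 among responders, 26:27:0 among nonresponders).

The class signal enters through two channels chosen because the pipeline's
features provably respond to them rather than by sampling feature space
directly:

* **T2w texture granularity** — a Gaussian random field whose in-plane
  correlation length is 2.2 px (responders) vs 1.1 px (nonresponders).
  Lengths are in pixels, not mm: texture granularity rides on the
  reconstruction grid, which keeps texture features comparable across
  centres with different pixel sizes. Amplitude (contrast 60) is
  class-independent — under fixed-bin-count discretization it is provably
  uninformative, and keeping it flat avoids pretending otherwise.
* **Tumour ADC level** — class means 0.92 vs 1.16 ×10⁻³ mm²/s.

Case-level heterogeneity uses Student-t(3) jitter (unit-variance scaled;
sd 0.13 on the ADC mean, sd 0.35 on log correlation length): most tumours
sit near their class mean, occasional atypical ones cross over, as real
cohorts show. Additionally 15% of each class are *borderline* tumours whose
parameters are pulled 70% toward the between-class midpoint — the
partial-response grey zone. These two mechanisms keep every finite cohort
from being linearly separable, which is what gives the AUC ≥ 0.99
overfitting gate something to act on. Background tissue sits between the two
classes in both channels (signal level and texture scale), so an imperfect
automatic mask leaks plausible neighbouring tissue that dilutes, rather than
systematically biases, the class signal.

The "automatic" mask is a seeded perturbation of the manual one: an in-plane
translation along a random direction brackets the requested Dice overlap,
then random boundary voxels are added or removed until DSC is within ±0.05
of target (default mean 0.8, spread 0.05; targets below 0.2 exercise the
exclusion rule).

The tabular generator (for selector-level experiments) plants 10 informative
features at standardized shift d (default 0.8), each with one duplicate at
r = 0.9, among label-independent noise drawn in equicorrelated blocks
(size 10, r = 0.9 within block) mirroring the heavy redundancy of real
radiomics catalogues. Block correlation is what lets stability resampling
suppress noise: correlation pruning removes all but one member per block per
resample and the surviving member varies, so no noise feature accumulates
enough selections, while an informative feature consistently beats its own
duplicate. With independent noise the stability filter cannot reject
label-independent features at all.

**What passing tests do and do not show.** The synthetic cohorts are
homogeneous ellipsoids with stationary texture; they contain no partial
volume effects, no bias fields, no motion or susceptibility artefacts, no
inter-scanner intensity scale differences beyond voxel geometry, and their
automatic masks err randomly rather than systematically (a real network
undersegments specific morphologies). Passing the end-to-end criteria shows
the pipeline's machinery is correct and that it recovers signal of the
designed kind at desk scale; it says nothing about clinical performance on
patient MRI, and the published cohort-level accuracies (68%/75%) are not
reproducible from synthetic data.

## Problem sizes

The seeded end-to-end study uses 20 construction + 10 validation cases per
cohort over 10 seeds, the selector-recovery experiment 20 tables of 67 × 157,
and the texture-oracle check 200 random slices — sizes chosen so a complete
replication runs on a single CPU in minutes while leaving every stated
property measurable.

## Known limitations

* 2D in-plane texture only (per-slice 2.5D averaging); no 3D 26-neighbour
  matrices, no filtered (wavelet/LoG) feature banks, no shape features
  beyond ROI volume.
* NIfTI affines are honoured only for voxel spacing; oblique acquisitions
  are treated as axis-aligned.
* Which four ADC first-order statistics the original procedure used is not
  stated; mean/SD/skewness/kurtosis is this package's declared, configurable
  default. Likewise the 25th GLCM feature is fixed here as sum variance.
* The exact identities of selected features are data-dependent and are
  diagnostics, not contracts.
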