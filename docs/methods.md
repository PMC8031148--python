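# Methods

This note documents the models implemented in `ssmbench`, the synthetic
cohort the test suite runs them on, and the numerical choices made where
the procedure leaves room.

## The SSM PCA-regression predictor

The predictor projects a training data array (variables × observations)
onto its leading principal components and regresses the outcome on the
component scores plus demographic covariates and an intercept.  Key
conventions:

- **Uncentered PCA.**  The grand mean pattern is *not* removed before the
  decomposition, so the first component usually absorbs the mean; a
  `remove_mean` flag exists for centered analysis.  The same convention is
  used for variance spectra.
- **Component count by AIC.**  Candidates are the contiguous leading sets
  1:N only (no subset search), N ≤ min(rank, 50, n − 5).  AIC is the
  Gaussian-likelihood form n·ln(RSS/n) + 2k with k counting the N slopes,
  the covariates, the intercept and the error variance.  Ties break toward
  smaller N.  N is re-selected independently on every training sample, so
  no information from a test half ever influences the selection.  Note a
  known property of plain AIC: each additional candidate component is
  accepted with probability ≈ P(χ²₁ > 2) ≈ 0.16 even under pure noise, so
  the selection is consistent in the median but overshoots occasionally;
  the test suite asserts exactly that behavior.
- **Covariates.**  Age (years), education (years), sex (0 = female,
  1 = male), used raw, in that order.  N = 0 degenerates to the
  covariates-only Reference model and is verified against an independent
  normal-equations solver.
- **Missing outcomes.**  Subjects without behavioral scores participate in
  every PCA but are excluded from regression rows and from PRESS; their
  predictions are still produced.
- **PRESS** is the *mean* of squared out-of-sample errors (angle-bracket
  averaging), not the sum, so values are comparable across test sizes.
- **Patterns.**  pattern = V(:,1:N)·β(1:N); covariate and intercept terms
  excluded.  The pattern is invariant to component sign flips.

## Monte-Carlo cross-validation

Splits are random subject-level 80/20 partitions, redrawn each iteration
(Monte-Carlo 5-fold cross-validation, not a fixed disjoint 5-fold).  With
240 subjects: 192 train / 48 test.  One `SplitPlan` is drawn per benchmark
run and shared verbatim — checksummed and asserted — by every modality,
the Vote, the Reference, and the CPM comparator, so PRESS distributions
are apples-to-apples.  Defaults are 1,000 iterations for SSM models and
200 for CPM; the test suite and acceptance script use 100–200.

## The CPM comparator

Edges correlating with the training outcome at two-sided p < 0.05
(uncorrected — the screen is internal to the model) are pooled into one
per-observation mean, on which the outcome is regressed by simple linear
regression.  Positively and negatively correlated edges are pooled
together by default; the classical split-sign variant is available via
`split_sign=True`.  An empty screen falls back to predicting the training
mean.  Covariates are excluded from CPM runs; the comparison against the
PCA model is restricted to connectivity data.

## Robustness Z-patterns

Across iterations, each variable's loading is summarized as
Z = mean / std (sample std, ddof 1; Z undefined and excluded where the
std is exactly 0), thresholded strictly at |Z| > 3 with negative loadings
retained by magnitude.  Edge patterns are average-pooled into
network-block matrices (14 × 14 under the default 264-node taxonomy),
with missing edges excluded from block means; the weighted block sum
equals the edge-pattern sum in the missing-free case.  Voxel masks on 3-D
grids are cluster-filtered: connected components (26-neighborhood by
default; 6 and 18 available) survive only if strictly larger than 100
voxels, with positive and negative super-threshold voxels clustered
separately.

An important caveat the test suite makes explicit: because resampling
iterations share ~80% of their subjects, a chance full-sample correlation
along a stable component keeps its sign across iterations, so the null
distribution of Z is wider than N(0,1) and an occasional null cohort
shows a non-trivial super-threshold fraction.  The Z-maps measure
within-cohort stability, not population-level significance.

## Time-series QC chain

Order is fixed: flag → replace → band-pass → residualize → correlate.

- **FD** is the Power convention: sum of absolute backward differences of
  the six rigid-body parameters, rotations converted to arc length on a
  50 mm sphere.  **RMSD** is the RMS over nodes of the frame-to-frame
  change of the percent-of-temporal-mean signal.  Frame 0 of both is 0.
- Volumes with FD > 0.5 mm **or** RMSD > 0.3% (strict inequalities) are
  replaced by per-node linear interpolation between the nearest clean
  frames; flagged runs at either end hold the nearest clean value.
- Band-pass is a zero-phase (forward-backward) Butterworth of order 4 per
  direction, 0.01–0.08 Hz at TR = 2 s; the first 8 frames (≈ the filter
  order) are discarded for settling.
- Nuisance residualization is per-node OLS on [FD, RMSD, extra series,
  intercept]; collinear columns are dropped with a warning; the operation
  is idempotent.
- Correlations are Fisher-Z transformed; |r| = 1 is clipped to
  atanh(1 − 1e-7) with a warning; zero-variance nodes yield missing edges
  that propagate to the conjunction mask.

## The synthetic cohort

The generator emulates the structure of a 240-subject adult-lifespan
cohort with 12 in-scanner tasks in 4 cognitive domains (3 tasks each),
264-node connectomes under a 14-network partition, voxel-like activation
maps, and 68-ROI volume/thickness vectors.

Generative model: each subject carries one latent ability factor per
domain, g ~ N(0,1).  Every modality expresses the factor along a planted
unit-norm pattern (dense, sign-heterogeneous — the regime where summing
screened edges loses information and CPM underperforms the PCA model),
on top of a fixed group mean, a subject-level trait component stable
across tasks, task-specific structure, and observation noise.  Outcomes
are sqrt(SNR)·standardize(g) + covariate effects + noise, with the noise
variance chosen so the factor carries exactly the configured fraction
(`snr_per_domain`, default 0.3 — a moderate brain-behavior effect) of
the unit outcome variance.

Defaults and what they encode:

| parameter | default | meaning |
|---|---|---|
| `trait_variance_fc` / `_act` | 0.02 / 0.005 | per-feature variance of stable subject differences; connectivity gets the larger trait share |
| `state_noise_fc` / `_act` | 0.25 / 0.5 | per-observation feature noise (Fisher-Z / contrast units) |
| `fc_base_mean`, `fc_base_sd` | 0.1, 0.1 | group-mean connectome level |
| `task_amplitude_fc` / `_act` | 0.05 / 1.0 | task-specific structure: connectomes are nearly task-invariant, activation topographies are strongly task-specific |
| `pattern_amplitude_*` | 1.0 (fc, act), 0.5 (struct) | loading of the ability factor on the planted pattern |
| `missing_behavior_fraction` | 0.05 | subjects missing all behavioral scores (missing completely at random at subject level) |

Demographics are matched to the emulated cohort's moments: age
51.10 ± 16.40 truncated to [21, 80], education 16.24 ± 2.37 truncated to
[9, 24], 110/240 male.  Covariate effects on the (standardized) outcomes
default to −0.2 (age), +0.15 (education), +0.1 (sex), jointly ≈ 7% of
outcome variance.

These choices reproduce the qualitative regime the pipeline is meant to
operate in: connectivity has the flatter (noisier) uncentered variance
spectrum — activation concentrates ~90% of its variance in 300 PCs versus
~65% for connectivity at test scale, and reaches 50% within ~10 PCs where
connectivity needs >100 — while both modalities carry the same recoverable
behavioral signal.

What the generator does **not** emulate: hemodynamics, spatial
autocorrelation of voxel maps, realistic task topographies, non-Gaussian
edge distributions, structured missingness.  Passing tests therefore
demonstrate correctness and calibration of the *pipeline*, not claims
about any particular empirical dataset.

Connectivity is generated directly in Fisher-Z edge space (the prediction
framework consumes Fisher-Z matrices); a separate band-limited ROI
time-series generator with injectable motion spikes serves as the fixture
for the QC chain.  Motion spikes are sustained steps, so FD crosses its
threshold exactly at the injected frames and spike recovery can be tested
as set equality.

## Problem sizes

Feature counts scale the compute quadratically-to-cubically, so the test
suite and acceptance script run the full 240-subject design at reduced
feature dimensions — 64 nodes (2,016 edges), 800 voxels, 100–200
iterations — where a complete benchmark takes seconds to minutes on one
CPU.  The nominal dimensions (264 nodes / 34,716 edges, 24,595 voxels,
1,000 iterations) are available through configuration.  One consequence
to keep in mind: planted-pattern recovery degrades with the
feature-to-subject aspect ratio (a BBP-type detectability threshold), so
recovery cosines quoted at desk scale do not transfer to the full edge
count at the same noise levels.

## Numerical details

- Degenerate inputs raise informative errors rather than returning NaN:
  all-zero PCA input, all-flagged frames, zero-variance z-score blocks,
  empty conjunction masks, rank-deficient designs (with the collinear
  columns named).
- Variance spectra of large arrays use a randomized top-k SVD
  (scikit-learn) with the total variance computed exactly from the
  Frobenius norm, so cumulative fractions are exact.
- PCA eigenvalues are squared singular values divided by the observation
  count; components below 1e-12 of the leading singular value are
  dropped.
- All stochastic components are driven by seeded `numpy` generators;
  identical seeds reproduce cohorts, split plans, and benchmark tables
  bitwise.
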