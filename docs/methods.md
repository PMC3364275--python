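# Methods

This note documents the models, conventions and design choices behind
`bandconn`, in the order the pipeline applies them, together with what the
synthetic-data experiments do and do not establish.

## Signal model and band decomposition

The pipeline's native input is a set of regional mean BOLD time series
(ROIs × timepoints per subject) with sampling interval TR. For imaging
input, `extract_regional_means` averages a 4D volume over each ROI label,
optionally restricted to a tissue mask (e.g. gray matter); labels whose
voxels all fall outside the mask yield an all-zero series and a warning
rather than an error, because downstream code handles zero-variance ROIs
explicitly. Slice-timing and motion correction are assumed done upstream;
the package deliberately starts at aligned volumes or extracted series.
The first `n_discard` volumes (default 10 in the study design this mirrors:
150 acquired → 140 retained) are dropped before any analysis.

Filtering and decomposition use an ideal rectangular mask on the real FFT.
A frequency bin belongs to an interval iff its centre frequency k/(N·TR)
lies inside it. Conventions, chosen so the sub-bands are an exact partition
of the band-passed signal:

- `bandpass_filter(lo, hi)` keeps bins on the **closed** interval
  [lo, hi]; the DC bin is always removed when lo > 0. The closed upper
  edge makes filtering over [0, Nyquist] the identity and makes the filter
  equal the union of a band partition whose last band is closed.
- `decompose_bands` assigns bins half-open [lo, hi) per band, with the
  **last band closed** at its upper edge, so every bin of the union
  interval lands in exactly one band and the components sum to the
  band-passed signal to machine precision.
- TR is explicit (default 2.0 s) because the bin-to-band mapping depends
  on it. With 140 timepoints at TR = 2 s the bin spacing is 1/280 Hz
  ≈ 0.0036 Hz, so each of the five default bands contains roughly four
  bins. Off-bin tones leak a few percent of power into neighbouring bands
  (ordinary spectral leakage); only bin-centred tones are assigned
  exactly.
- The printed band edges (0.025/0.039/0.054/0.068/0.082/0.100 Hz) are kept
  verbatim as defaults even though they are not an exact equal split of
  the interval; `band_edges="equal-split"` derives exact fifths instead.

## Connectivity networks

Per band, the network is the matrix of sample Pearson correlations between
band-limited ROI series, Fisher-transformed (z = arctanh r) to normalize
the coefficient distribution; z of an r estimated from n timepoints is
approximately normal with sd 1/√(n−3), and networks carry n for that
purpose. Conventions: r is clipped to ±(1 − 1e−7) before arctanh so
perfectly correlated pairs stay finite; the diagonal is fixed at 0;
zero-variance ROIs (sd below 1e−12 of the series scale, e.g. fully masked
regions) get correlation 0 with everything and a warning. Negative
z-weights are retained in the stored network — they are discarded later, at
feature computation, matching the order of operations the pipeline
documents ("positive values only during clustering-coefficient
computation").

## Clustering-coefficient features

Each network reduces to one number per node: the geometric-mean (Onnela
form) weighted local clustering coefficient over positive weights,

    C_i = Σ_{j≠h, j,h≠i} (ŵ_ij ŵ_ih ŵ_jh)^{1/3} / (k_i (k_i − 1)),

with ŵ = W/max(W) rescaled by the **per-network** global maximum and k_i
the number of positive-weight neighbours. Negative weights are treated as
absent edges and do not count toward degree; nodes with k_i < 2 get C_i = 0
(undefined denominator); an all-nonpositive network yields all zeros.
Per-network rescaling makes C invariant to a global weight scaling but
means coefficients are self-normalized per subject and band — a
deliberately documented choice, as it affects cross-subject comparability.
Features are concatenated band-major (all ROIs of Band1, then Band2, …),
giving bands × ROIs features in multi-spectrum mode and ROIs features in
full-spectrum or single-band mode.

## Feature selection and classification

Nested full leave-one-out cross-validation (LOOCV):

- **Outer loop** (N folds): subject s is held out entirely.
- **Inner loop** (N−1 folds): each remaining subject v is held out once;
  the N−2 others are the inner training set. Features are standardized
  with inner-training mean/sd only, ranked by |Pearson correlation with
  the ±1 labels| (zero-variance features rank last, ties by ascending
  index), and the top_m enter SVM-RFE.
- **SVM-RFE**: backward elimination; every candidate single-feature
  removal is scored by the leave-one-out error of an RBF-kernel C-SVC on
  the remaining features, the smallest-error removal is committed (ties:
  remove the worse-ranked feature), and the subset with minimal LOO error
  along the whole path — including the full set — is selected, preferring
  the smaller subset on ties. With an RBF kernel the error is genuinely
  removal-dependent even for duplicated features (removing a copy changes
  the effective kernel width), so the smallest-subset preference only
  bites on exact error ties.
- **Grid search** over (C, γ): per inner fold, the grid point maximizing
  the inner-LOO AUC at the optimal subset is chosen; correctness on the
  inner held-out subject breaks ties, then smaller C, then smaller γ. The
  default grid is C ∈ {2⁻⁵,2⁻³,…,2⁵}, γ ∈ {2⁻⁵,…,2³}; the `fast` profile
  uses C ∈ {0.5, 8}, γ ∈ {0.125, 1}.
- **Ensemble decision**: subject s receives the mean of the N−1 inner
  models' real-valued decision scores (not hard votes, to preserve ROC
  resolution) and is predicted patient iff the mean is positive. Accuracy,
  the threshold-sweep ROC and the trapezoidal AUC (an exact identity with
  Mann–Whitney U/(n₁n₂), ties counted half) are computed over the pooled
  outer folds, and selection frequencies count how many (outer, inner)
  folds included each feature in their optimal subset.

Information hygiene is auditable: every fitted model's training indices are
recorded and hashed, and `audit_hygiene` verifies that no outer-fold test
subject appears in any training set of its own fold. The whole procedure is
deterministic given the feature table and grid.

**Class weighting.** By default classes are unweighted. The optional
`class_weight="balanced"` applies inverse-frequency weights to the SVM
penalty (per-class C scaled by n/(2·n_class)). This matters for
leave-one-out calibration: removing the test subject always tilts the
training majority against its class, which under label permutation biases
LOOCV accuracy *below* chance (a known small-sample artifact — pessimistic,
not optimistic, so it cannot fake discriminative power). The package's null
calibration protocol therefore measures the permutation null on a
**balanced** cohort (chance is unambiguously 50%) with balanced weights;
the unweighted default on the same null sits a few points below 50%.

**SVM solver.** The nested structure costs on the order of N³ × top_m² SVM
fits per run, on problems of a few dozen samples. Fits use a compiled SMO
solver (libsvm's maximal-violating-pair working-set algorithm, numba),
warm-started across leave-one-out folds from the full-data dual solution;
for a positive-definite kernel the dual optimum is unique, so warm starting
changes only iteration counts. When no free support vector exists, the bias
is the midpoint of its KKT-feasible interval (libsvm's convention). A test
asserts agreement with `sklearn.svm.SVC` decision values to 1e−6 at tight
tolerance. KKT tolerance is 1e−3 (libsvm's default) inside RFE loops and
1e−6 for final models.

## Synthetic cohorts

`generate_cohort` emulates the study conditions: by default 12 patients and
25 controls, 116 ROIs, 140 timepoints at TR = 2 s. Each subject's ROI
series is a sum of independent band-limited components plus white noise.
Per band, a designated ROI set shares an equicorrelation (single latent
factor for ρ ≥ 0, explicit Cholesky otherwise); in exactly one band the
patient group's coupling is `within_band_coupling − effect_delta`.
Correlation is imposed *before* band-limiting, so the same spectral
projection acts on all ROIs and the target correlation is preserved in
expectation within the band. Components are rescaled to unit expected
variance (counting real spectral degrees of freedom), making `noise_sd`
interpretable relative to per-band signal; the default 0.5 puts white noise
at a quarter of one band's variance — optimistic for raw BOLD but
reasonable for averaged regional series. Defaults: coupling 0.6, delta 0.4,
affected band Band3.

What the generator does *not* emulate: hemodynamic autocorrelation, 1/f
spectra, head motion, physiological noise structure, spatial smoothness, or
site effects. Passing tests therefore demonstrate the pipeline's
correctness and its sensitivity to band-localized correlation differences —
not clinical performance on real fMRI. The "unmasked" acquisition condition
of voxel pipelines is approximated for tabular input by an additive common
noise series per subject (`add_common_contamination`), which inflates all
pairwise correlations the way unmasked non-neuronal signal does.

## Problem sizes in the test suite and acceptance script

Study-scale runs (37 subjects × 580 features with a full grid) cost hours
per replicate; the package's replicate-based experiments use desk-scale
designs chosen once:

- **Effect recovery**: 10 replicate cohorts, 13+13 subjects, 12 ROIs of
  which 8 coupled, coupling 0.6 → 0.2 in Band3 for patients, 140
  timepoints, noise 0.5; top_m = 6, grid {0.5, 8} × {0.125} — checking
  that multi-spectrum accuracy ≥ full-spectrum, that Band3 attains the
  best single-band accuracy (in ≥ 90% of replicates each), and that
  selected features concentrate in Band3 (median fraction > 1/5).
- **Null calibration**: one null cohort (delta = 0), 8+8 subjects, 40
  label permutations, balanced class weights; mean LOOCV accuracy within
  two standard errors of 50%.

`scripts/acceptance.py` runs one effect-recovery cohort (all seven
approaches) and the null calibration at the same sizes, deriving every seed
from `--seed`.

## Known limitations

- The RFE inner LOO reuses the inner-training standardization (it is an
  error *estimator*, not the outer test path; outer hygiene is audited).
- Accuracy from LOOCV on ~26 subjects has a sampling sd of several points;
  single-cohort accuracies should be read accordingly.
- Band-limited correlations at 140 timepoints rest on ~4 Fourier bins per
  band (~8 effective dof), so per-band networks are intrinsically noisy;
  this is a property of the design the pipeline mirrors, not of the
  implementation.
- The ideal FFT mask has sharp spectral edges (sinc-like impulse
  response); it is the right tool for an exact spectral partition, not a
  general-purpose filter.
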