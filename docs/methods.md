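# Methods

This note documents the models, conventions and numerical choices behind
`ictalsel`, and what the synthetic-data study design does and does not
establish.

## Synthetic recordings

The generator produces multichannel signals that reproduce the gross
statistics relevant to epoch-level seizure detection, not physiological
EEG. Background activity per channel is independent 1/f^α colored noise
(α = 1, RMS 20 µV nominal) plus a 10 Hz sinusoid at 5 µV with random phase
— enough that all five analysis bands carry non-degenerate power. Seizures
are placed uniformly at random with a minimum 4 s gap (twice the analysis
window, so no epoch can straddle two seizures) using the spacings
construction, which is exact and cannot fail by rejection; infeasible
requests raise immediately. Within each annotated interval, the channels
listed in `ictal_spec` receive an additional rhythm (default: 6 Hz at 4×
the alpha amplitude) under a raised-cosine on/off ramp over the first and
last 10% of the interval, so onsets are not step discontinuities.

Because the planted effect is an amplitude increase in a known channel and
band, the set of features that *must* be discriminative is known by
construction: the amplitude-sensitive metrics (FS1: var, rms, range; FS2:
min, iqr, mad, sd) of the planted band and of the complete 0.5–30 Hz band
on that channel. `ground_truth_features` returns exactly this set, which
is what parameter-recovery tests score rankings against.

What the generator does **not** emulate: inter-subject and inter-seizure
variability, artifacts (EMG, eye blinks, electrode pops), non-stationary
background, spatially correlated noise across channels, or realistic
seizure morphology (spike-wave complexes, frequency evolution). Passing
the planted-recovery tests therefore shows that the ranking machinery
recovers a genuine band-limited amplitude effect under class imbalance —
it does not certify performance on clinical recordings.

Amplitude units are nominal microvolts; the absolute scale is irrelevant
because evaluation min–max-normalizes every feature.

## Preprocessing

- **Montage.** Recordings are generated directly in bipolar form (the
  channel sets of the public seizure databases are bipolar); a monopolar
  mode plus `to_bipolar` with the standard 18-pair longitudinal montage
  exists to exercise the conversion. Electrode name matching is
  case-insensitive.
- **Filters.** 2nd-order Butterworth high-pass at 0.5 Hz, then an IIR
  notch (quality factor 30 — a standard narrow power-line notch; the
  design is otherwise unconstrained) at 50 or 60 Hz, then 2nd-order
  Butterworth band-passes for the five bands. All filters are applied
  forward–backward (zero-phase), which keeps epoch boundaries aligned
  with the annotations at the cost of doubling the effective filter
  order; a symmetric pulse stays symmetric to within the edge-padding
  residual (~1e-4 relative).
- **Epoch labeling.** An epoch is ictal iff at least 50% of its samples
  lie inside an annotated interval. Ictal epochs are cut with a 1 s
  stride (50% overlap of the 2 s window) inside each interval; non-ictal
  epochs tile the record without overlap; tiled epochs with an in-seizure
  fraction in (0, 0.5) are discarded entirely rather than labeled,
  avoiding label noise at seizure boundaries.
- **Rebalancing** keeps every ictal epoch and subsamples non-ictal epochs
  uniformly (seeded, without replacement) to at most 9 per ictal epoch.

The continuous recording is filtered first, then epoched, then
band-decomposed per epoch; the complete 0.5–30 Hz copy goes through the
same band-pass machinery as the four sub-bands for uniform treatment.

## Feature metrics and conventions

All metrics operate on a 1-D epoch (512 samples at 256 Hz by default).
Degenerate inputs never produce NaN:

- skewness and kurtosis of a constant epoch are 0 (the moment ratios are
  0/0); kurtosis is *excess* kurtosis (normal → 0);
- Hjorth mobility/complexity of a constant epoch are (0, 0);
- spectral metrics of a zero-power epoch are (0, 0);
- sample entropy uses Chebyshev matching with tolerance r = 0.2·σ; with
  σ = 0 equal samples match and SampEn = 0; if no template pair matches
  at either length the value is capped at ln(n);
- zero crossings count strict sign changes; an exact zero inherits the
  previous sign so it is never counted twice.

The PSD is a single Hann-windowed periodogram (0.5 Hz resolution on a 2 s
epoch); Welch averaging has nothing to average at this epoch length.
Median frequency is the smallest frequency at which cumulative power
reaches half the total.

Correlation pruning scans columns in order and drops the *later* column of
any pair with |r| > 0.95 against an already-retained one — the absolute
value is used so anti-correlated duplicates are removed too, and the
deterministic tie-break makes the operation idempotent. Zero-variance
columns correlate with nothing; they are retained but flagged in the audit
list.

## Ranking methods

Shared conventions: scores are non-negative (absolute values taken where a
method is signed), per-instance attributions are aggregated abs-first then
averaged (abs-first prevents sign cancellation across instances), and rank
ties break stably by original column index. Whenever ranking requires
model training, a seeded stratified 50% subsample of the data is used,
min–max scaled.

- **DT**: scikit-learn's normalized Gini importances of a single CART tree
  (min 4 samples per split) — identical to the node-probability-weighted
  impurity-decrease sum, verified in tests against a separable-stump
  oracle.
- **SVM**: |w| of a linear soft-margin SVM, C = 1.
- **LIME**: perturbations x + ε·σ with ε ~ N(0, I), 1000 per explained
  instance; kernel weights exp(−‖ε‖²/w²) with width w = 0.75·√M (standard
  practice for tabular explainers); surrogate = ridge regression (α = 1)
  on the standardized perturbations against the model's positive-class
  probability, so coefficients are commensurable across features.
  Continuous values are not discretized.
- **Kernel SHAP**: coalitions are fully enumerated for M ≤ 12; above that,
  all size-1 and size-(M−1) coalitions are included and the remainder
  (budget 2M + 2048 by default) is sampled from the Shapley-kernel
  distribution over sizes, in which case the regression is unweighted
  within the sample. Absent features are imputed from k-means centroids
  (k = 50) of a training subsample, averaging the model output over *all*
  centroids — a deterministic choice, preferred over sampling one donor
  instance per evaluation because it makes attributions reproducible and
  exactly testable. The additive constraint Σφ = f(x) − E_bg[f] is
  enforced by eliminating the last coefficient, so full enumeration
  reproduces exact Shapley values of the imputation value function to
  machine precision.
- **ERF**: a 10-tree random forest (min 2 samples per split) is trained on
  half the ranking subsample; permutation importance (5 repeats, mean
  accuracy decrease = mean error increase) is measured on the disjoint
  other half — a held-out-set reading of "permutation importance on a
  separate dataset", chosen over out-of-bag scoring.
- **RR**: r(f) = 1/Σ_j 1/r_j(f) over the five base rankings; the stored
  score is Σ_j 1/r_j(f) so that the descending-score ordering convention
  holds (ascending r(f) ⇔ descending stored score).

LIME and SHAP explain the positive-class probability of the same
classifier family that is later evaluated with the ranking; the pipeline
wires that pairing per classifier.

## Evaluation

Min–max scaling is fitted per training fold only; a constant training
feature maps to 0 everywhere and test values may leave [0, 1] (no
clipping). Folds are *stratified* 2-fold splits, reshuffled each of the 5
repetitions — with 1:9 imbalance an unstratified split risks a fold
without ictal epochs. Rankings are computed once up front, not per fold.
F1, sensitivity and accuracy are computed for the ictal (minority,
positive) class from confusion counts accumulated over the 10 folds;
zero-denominator cases return 0. The ANN runs a fixed 200 epochs (loss
tolerance 0, patience = max epochs) so training length is deterministic.

The elimination schedule keeps [n, every multiple of 50 below n, 25, 12,
6, 1], deduplicated and descending.

**5×2cv F-test.** F = Σ_ij d²_ij / (2 Σ_i s²_i) referred to F(10, 5),
with s²_i the two-value sample variance of repetition i. Degenerate
cases: all d = 0 → F = 0, p = 1; zero variance with nonzero differences →
reported as infinitely significant and flagged. Note that the statistic
is structurally *conservative*: its numerator contains the same
half-difference sum of squares that forms its denominator, so under an
ideal iid-normal null the exact rejection probability at the nominal 0.05
level is P(F(5,5) > 2·F_crit(10,5) − 1) ≈ 0.0175, and the measured
type-I error of the packaged null simulation (Gaussian naive Bayes vs LDA
on diagonal-covariance Gaussian data, both correctly specified and hence
equal-accuracy) is ≈ 0.02. The test therefore under-rejects rather than
over-rejects; the property the suite guarantees is the one-sided bound
(never anticonservative).

## Problem sizes

The packaged study runs at desk scale: 4 bipolar channels, 10-minute
recordings with four ~30 s seizures (≈ 350 epochs after rebalancing, 160
FS1 features before pruning), 25 explained instances for LIME and 8 for
kernel SHAP (300 sampled coalitions), and 500 simulated dataset pairs for
the F-test calibration study. These sizes were chosen so the full study
re-runs in minutes on one CPU while keeping every structural condition
(sampling rate, window length, overlap, imbalance, band set, method
configurations) identical to the full-scale setting; the 21-channel /
840-feature layout is exercised separately by the layout identities.

## Known limitations

- Headline classification scores on the clinical databases are not
  reproducible here by design: the package substitutes a synthetic study
  with known ground truth.
- The EDF reading hook is a convenience passthrough (via mne) and is not
  validated against the quirks of real clinical EDF exports.
- Whether epoching should precede or follow band separation is
  underdetermined in the field's descriptions; this package filters the
  continuous recording, epochs, then band-decomposes each epoch.
- Correlation pruning is applied to the full dataset before splitting
  (matching the narrative order of the emulated protocol); a
  training-fold-only entry point exists for leakage-sensitive uses
  (`prune_correlated` on any FeatureMatrix).
- k-means (not the classifiers) is the only stage whose determinism
  depends on scikit-learn's internal seeding; it is seeded explicitly.
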