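# Methods

This document describes the analysis model implemented by `pdmri`, the
synthetic-cohort generator used to validate it end to end, and the
numerical choices behind both.

## 1. Analysis pipeline

The package implements a multi-modal MRI classification protocol for
separating early Parkinson's disease patients from healthy controls:
three resting-state fMRI metrics and three structural tissue metrics are
summarised over a 116-region anatomical parcellation, screened by
per-feature t-tests, fused, and classified with a sigmoid-kernel SVM under
leave-one-out cross-validation (LOOCV).

### 1.1 Functional metrics

BOLD preprocessing: the first 10 frames of the 195-frame series (TR = 2 s)
are discarded, leaving 185 analysis frames. Subjects whose motion
parameters exceed 2 mm translation or 2° rotation on any axis are
excluded. All voxelwise metrics are computed inside a brain mask
(mean-intensity threshold) and the functional series is band-pass filtered
to 0.01–0.1 Hz.

- **ALFF** — amplitude of low-frequency fluctuations: the one-sided
  amplitude spectrum averaged over the in-band FFT bins, voxelwise.
- **ReHo** — regional homogeneity: Kendall's coefficient of concordance
  *W* over each voxel's 27-voxel neighbourhood (the voxel plus its 26
  face/edge/corner neighbours), computed on the ranks of the time points
  with average ranks on ties and no tie-correction (the classic ReHo
  convention):

      W = (Σ_t R_t² − n·R̄²) / (K²(n³ − n)/12)

- **RFCS** — regional functional connectivity strength: region-mean time
  series are extracted for the 116 atlas regions, the six motion
  parameters and the whole-brain mean signal are regressed out (nuisance
  regression is applied on this path only), and each region's RFCS is the
  mean Pearson correlation of its residual series with the other 115
  regions.

ALFF and ReHo maps are divided by their mask mean (mask-mean exactly 1)
and then averaged within each atlas region, giving a 116-vector per
metric per subject.

### 1.2 Structural metrics

GM, WM and CSF tissue probability maps are smoothed with a 10-mm-FWHM
Gaussian kernel (FWHM = σ·2√(2 ln 2), implemented as a separable filter in
voxel units of the map's stated voxel size) and averaged within the atlas
regions: three more 116-vectors per subject.

### 1.3 Feature selection, fusion, classification

For each LOOCV fold (46 folds for the default 19 + 27 cohort):

1. **Selection** on the 45 training subjects only: a two-sample pooled-t
   test per (metric, region) feature; features with p < 0.05 are retained.
   No multiple-comparisons correction is applied (deliberately, following
   the protocol). If nothing passes in any metric, the single smallest-p
   feature is kept so the fold can proceed (logged).
2. **Fusion**: retained features are concatenated in the fixed order
   ReHo, ALFF, RFCS, GM, WM, CSF.
3. **Standardisation**: z-scoring with the training fold's mean/SD.
4. **SVM**: C-SVC with the sigmoid kernel tanh(G·⟨u,v⟩). C and G are
   searched exhaustively over the 21 × 21 grid 2⁻¹⁰ … 2¹⁰, each pair
   scored by *exact* inner leave-one-out on the training fold ("nested"
   mode, the default). Ties in inner accuracy resolve to the
   lexicographically smallest (C, G). "global" mode instead fixes one
   (C, G) for all folds by the same criterion on the full cohort.
5. The held-out subject's **index score** is the oriented decision value
   (positive = case); a score of exactly 0 resolves to control.

Outputs: accuracy / sensitivity / specificity in percent, the ROC curve
and AUC over the index scores (AUC equals the Mann-Whitney statistic with
ties counted ½), a per-fold table of selected-feature counts per metric,
and a selection-frequency report listing the features selected in *more
than half* of the folds (count > 23 of 46) with whole-cohort t and p
values.

## 2. Synthetic cohort generator

Real patient data cannot ship with the package, so validation uses a
desk-scale generator (`pdmri.synthetic_cohort`) that writes complete
cohorts — 4-D BOLD-like volumes, tissue maps, motion files, an atlas and a
manifest — with controllable group effects per metric channel.

### 2.1 Signal model

Every voxel v in region r carries

    x_v(t) = a_r · ( w1_r · reg_r(t) + Σ_k W_rk · net_k(t) + w3_r · priv_v(t) )
             + (a_r/a0) · σ_n · ε_v(t) + baseline

where `reg_r` (one per region), `net_k` (K = 4 network signals; regions
join them round-robin) and `priv_v` (one per voxel) are independent
band-limited unit-RMS noise signals, ε is white noise, and
w1² + ΣW² + w3² = 1. The three functional dials are orthogonal by
construction:

- **amplitude a_r → ALFF**: the mixture is unit-RMS and the white noise
  scales with a, so amplitude changes neither synchrony nor coupling;
- **within-region synchrony w1 → ReHo**: `reg_r` is shared by the
  region's voxels, raising neighbourhood concordance;
- **network coupling W → RFCS**: shared network signals raise
  inter-regional correlation. An RFCS implant adds coupling *to all K
  networks* (weight d·SD/√K each) — a component the target shares with
  every region, which is what the mean correlation measures. w1 is
  adjusted to keep the total shared power constant so the implant does
  not leak into ReHo.

Tissue maps are per-region levels plus smooth spatial noise; tissue
implants shift the region's level. Motion traces are clipped random
walks; designated "violator" subjects get a 3-mm jump to exercise the
exclusion rule.

Group effects are stated in pooled-SD units of the underlying parameter
(amplitude, synchrony, coupling, tissue level). The default recipe
implants ±3 SD in six known regions, one per channel.

### 2.2 Design choices forced by the protocol

Three generator properties were found to be load-bearing; each is the
result of a measured failure mode, not a tuning exercise:

- **Compact rectangular parcels.** ReHo is a 26-neighbourhood statistic:
  a within-region synchrony change only transfers to regional ReHo in
  proportion to the squared fraction of each voxel's neighbourhood lying
  in its own region. The atlas therefore splits the grid by recursive
  proportional bisection into near-cubic rectangular blocks (mean squared
  in-region neighbourhood fraction ≈ 0.32 at the default size); thin or
  snake-shaped parcels (≈ 0.14) suppress the transfer almost entirely.
- **Continuous in-band spectra.** Band signals are synthesised in the
  frequency domain (every rFFT bin in 0.015–0.095 Hz, random phases,
  exact unit RMS). Sparse line spectra (e.g. 12 sinusoids) leave so few
  temporal degrees of freedom that realised-variance noise dominates
  between-subject ALFF spread and inter-regional sample correlations
  (SD ≈ 0.2) drown coupling implants.
- **A background shell around the atlas.** The default grid is 20³ with
  the 116 parcels in the 18³ interior and a 1-voxel in-mask background
  shell (label 0) sharing one physiological component. This emulates the
  substantial extra-atlas tissue inside a real brain mask. It matters
  because the protocol regresses the whole-brain mean out of the ROI
  series: if the mask support equals the atlas support exactly, the
  global signal *is* the region-weighted mean of the ROI series, the
  residual covariances of each region with all others sum to ~0, and the
  signed mean correlation (RFCS) is pinned near −1/(N−1) no matter what
  is implanted. With the shell, the measured RFCS transfer of a +3 SD
  coupling implant is d ≈ 2.1 with global-signal regression (≈ 2.8
  without it; the regression itself costs about a quarter of the effect —
  a property of the reference protocol being modelled, reported rather than
  compensated).

### 2.3 Known limitations

- The remaining attenuation of the RFCS transfer (≈ 2 observed vs 3
  nominal) is sampling noise of 185-frame correlations; it cannot be
  removed at fixed record length.
- ReHo implants leak slightly into RFCS (changing w1 changes the
  region-mean variance that normalises the correlations); documented, not
  compensated.
- Uncorrected p < 0.05 screening admits ≈ α × 696 ≈ 35 chance features
  per fold alongside the implants; the achievable recovery accuracy is
  therefore below the single-digit-feature oracle (measured: ≈ 93 % vs
  ≈ 96 % for an oracle using only the six implanted features). This is a
  property of the reference protocol, reproduced deliberately.
- The generator has no spatial autocorrelation within regions beyond the
  shared components, no physiological confounds on the motion traces, and
  block-shaped regions rather than anatomical shapes.

## 3. Numerical choices

- **Kendall's W**: computed from average ranks with the classic
  (uncorrected) denominator, validated against a literal textbook
  implementation to 1e-12 over randomised instances including ties.
- **Band-pass filter**: FFT-domain masking of the rFFT bins outside the
  band (linear-phase, idempotent); validated on pure sinusoids.
- **Gaussian smoothing**: separable filter with σ = FWHM/(2√(2 ln 2))
  per-axis in voxel units; validated via mass preservation and
  second-moment spread.
- **SVM**: the exhaustive grid needs hundreds of thousands of small SVM
  fits per run, so the pinned scikit-learn low-level libsvm binding is
  called directly when available (~30× faster than the public estimator
  at this size), with an automatic public-`SVC` fallback. The low-level
  `predict` returns class *indices* into the sorted unique labels, which
  are mapped back to the ±1 labels; decision-value orientation is
  calibrated against libsvm's own predictions. Equivalence with the
  public estimator is unit-tested.
- **Exact inner LOO**: each (C, G) pair is scored by literally refitting
  on each inner training subset. Approximations (libsvm's built-in CV,
  the α-based LOO shortcut) were tested and rejected: both disagree with
  the exact loop for the indefinite sigmoid kernel.
- **Determinism**: every stochastic step derives from
  `numpy.random.SeedSequence` fan-out of a single seed; cohorts are
  bitwise reproducible subject by subject.
- **Permutation null**: the acceptance checks use 3 label permutations
  (each nested-LOOCV run costs ~1 minute single-threaded) with an
  acceptance band sized for that replicate count; LOOCV under permuted
  labels runs at or somewhat below the majority-class rate (58.7 % for
  27:19).
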