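# Methods

## Signal model and derived modalities

Diffusion-weighted signal is modelled as mono-exponential,
S(b) = S0·exp(−b·D), with b in s/mm² and D in mm²/s.  The ADC map is the
per-voxel ordinary least-squares fit of ln S against b (slope −D,
intercept ln S0), including b = 0.  OLS was chosen over maximum-likelihood
alternatives because it is deterministic and exact on noiseless
mono-exponential input, which gives the test suite a machine-precision
oracle.  Signals are clamped to ≥ 1e−6 before the log; negative fitted D
is clamped to 0; a voxel whose signal is zero at every b yields D = S0 = 0
and increments a warning counter.

CHB-DWI is the deterministic extrapolation S0·exp(−b_target·D) of that fit
to b_target = 2000 s/mm² and refuses b_target at or below the largest
acquired b: it is strictly an extrapolator.  Extrapolation amplifies
delineation because the tumour/healthy intensity ratio grows as
exp(b·(D_h − D_t)): ≈ 3.3 at the acquired b = 1000 versus ≈ 11 at the
computed b = 2000 for typical D values (1.8e−3 vs 0.6e−3 mm²/s).

CDI mixes the acquired signals across all b-values within a local
subvolume V(x).  The joint density of the signals over V(x) is not
prescribed anywhere usable, so the package uses the empirical (delta-mass)
estimator, under which the mixing integral reduces to a local mean of
cross-b products: CDI(x) = mean over y ∈ V(x) of Πᵢ Sᵢ(y).  The estimator
sits behind a single function so a different density model can replace it.
V(x) defaults to a 3×3×1 box (in-plane radius 1): slices are 3 mm thick
against ~1.56 mm in-plane spacing, so through-plane mixing is off by
default.  At image borders V(x) is clipped rather than padded — padding
would invent signal.  b = 0 is included in the product; excluding it only
rescales the map by S0 and does not change delineation.

Contrast/delineation between tumour and healthy gland is summarized by the
tumour/healthy mean-intensity ratio and the normalized mean difference
|μ_t − μ_h| / μ_h.  These are well defined on noiseless input, where
within-class variance can be exactly zero and any pooled-σ effect size
degenerates.  Note that with lesions only a few voxels across (the
realistic ~1.5 % tumour fraction), most tumour voxels are boundary voxels,
so the 3×3 CDI mixing dilutes a variance-normalized contrast even while
its mean-ratio delineation stays far above ADC's.

## Texture features

Per modality and per 3×3 in-plane window centred in the gland (2-D
windows: at 3 mm slices a 3-D window would be strongly anisotropic), the
96-feature vector is 4 first-order moments + 72 co-occurrence statistics +
12 Gabor magnitudes + 8 Kirsch gradients.

* First order: mean, population standard deviation, skewness and excess
  kurtosis; moment ratios of a constant window are defined as 0.
* Co-occurrence (GLCM): grey levels are quantized to 16 bins by min–max
  scaling over the gland per modality (per-window scaling would destroy
  inter-window contrast); matrices are built at offset distance 1 in four
  directions (0°, 45°, 90°, 135°), symmetrized and normalized.  The 18
  statistics per direction follow the standard Haralick definitions with
  entropies in bits; "information measure of correlation" is variant IMC1.
  For IMC1 the term HXY1 = −Σ p_ij log(p_i p_j) is computed through the
  algebraic identity HXY1 = HX + HY (exact for any joint distribution).
  A constant window yields energy 1, contrast 0, and correlation and the
  entropy-type statistics 0.
* Gabor: 3 frequencies {0.1, 0.25, 0.4} cycles/pixel × 4 orientations
  {0°, 45°, 90°, 135°}; the complex kernel is applied to the whole slice
  (reflect boundary, FFT convolution) and the mean response magnitude is
  pooled per window, avoiding window-edge artefacts.  The filter bank's
  parameters are a package choice; only the 3 × 4 count is fixed.
* Kirsch: the classic eight ±5/±3 compass kernels; the feature is the
  maximum absolute response over the window, per direction.

A window inherits the label of its centre voxel (pixel-based ground
truth).  Windows are restricted to centres inside the gland and far enough
from the slice border to fit.

## Feature selection

Mutual information is the histogram plug-in estimate in bits, after
equal-width discretization into 16 bins per column (matching the GLCM
level count); a constant column carries zero information.  mRMR ranks
greedily with the difference (MID) combination: first the feature with
maximal MI with the class, then repeatedly the feature maximizing
MI(f; c) − mean over selected g of MI(f; g).  Ties break lexicographically
by feature name for determinism.

The subset size m is chosen by sweeping prefixes of the ranking (default
grid: steps of 10 up to 96 per modality) and scoring each prefix with a
patient-grouped cross-validated SVM; the best m maximizes the configured
criterion, ties to the smallest m.  Two tractability devices, both
deterministic: (1) MI is estimated from a stratified row subsample capped
at 8000 (all cancerous rows kept) — at cohort scale tens of thousands of
rows change the ranking negligibly; (2) the greedy stage runs only to the
largest grid entry below the full feature count, because a prefix of size
p is the full feature set regardless of internal order; later positions
are completed in descending marginal-relevance order.

## Texture feature models

A model (TFM) is built in stages: per-modality selection of the best
subset, concatenation of the winners, and a second selection pass over
the pool under the same criterion, followed by training the final SVM.
The pooled stage sweeps a compact 4-point log-spaced size grid — the pool
can reach 768 features and each candidate size costs a cross-validated
SVM.  The six named compositions (TFM1 = T2w+ADC … TFM6 = all eight
modalities) are enforced at construction.

Models are compared per metric by a two-sided Wilcoxon signed-rank test on
paired per-patient values: exact null distribution up to 12 non-zero
pairs, normal approximation with continuity correction above.  All-zero
difference vectors are reported as p = 1 with a degenerate flag.  Patients
without cancerous samples have undefined sensitivity and drop out of that
metric's pairing only.

## Classification and evaluation

Validation is leave-one-patient-out: one fold per patient, so no window of
a test patient influences training.  Features are standardized with
training-fold statistics only and fed to an RBF SVM with class weights
inversely proportional to class frequency — at ~1 % positives an
unweighted fit collapses to the majority class.  C = 1 and gamma = 'scale'
are library defaults, configurable.  Training folds can be capped
(default 3000 samples, all positives kept, healthy windows subsampled
deterministically) to keep kernel fits tractable at cohort scale.

The operating threshold is chosen on training scores: Youden's J by
default, or a quantile policy pinning the prioritized training rate
(sensitivity or specificity) at a target (default 0.9) for the two
clinical scenarios (screening favours sensitivity; surgery planning
favours specificity).  Pooled sensitivity/specificity/accuracy use each
fold's own threshold; AUC is trapezoidal over the pooled decision scores
and equals the Mann–Whitney statistic with ties counted ½.  A rate whose
denominator class is absent is reported as NaN, never 0.  95 % confidence
intervals are percentile bootstrap over patients (default 2000 resamples,
seeded), recomputing each metric on the pooled samples of each resample;
a metric undefined in more than half the resamples gets an undefined CI.

## Phantom

The generator emulates: Table-style two-grid geometry (analysis on the
DWI grid, default 1.56×1.56×3 mm³ voxels; T2w generated on the same grid
and optionally resampled), an ellipsoidal gland with 0–2 ellipsoidal
lesions nested inside it, per-patient tissue parameters drawn uniformly
from literature-plausible ranges (healthy D 1.4–2.0e−3, tumour D
0.5–0.9e−3 mm²/s, S0 800–1200), a 25 % T2w signal drop in lesions, a
smooth ±5 % multiplicative intensity inhomogeneity field, Rician
(magnitude-image) noise with σ = 10 against S0 ≈ 1000 (mild, SNR ≈ 100 at
b = 0; scanner noise statistics are not published, so σ is a free
parameter), a 1.5 % target tumour fraction, and a lesion-count prior
(0.15, 0.45, 0.40) so cohorts contain lesion-free patients (the clinical
cohort had 3 of 20).  Everything is deterministic given (seed,
patient index).

What the phantom does **not** emulate: zonal anatomy (peripheral vs
transition zone), benign confounders (BPH, prostatitis) that mimic tumour
signal, motion/distortion, multi-compartment (IVIM/kurtosis) diffusion,
and inter-sequence misregistration.  Because lesions differ from healthy
gland in clean mono-exponential D, window-level separation is much easier
than in clinic: passing pipelines here demonstrate correctness of the
machinery and the *direction* of the modality comparisons, not clinical
performance levels.

## Problem sizes

Default cohorts are 20 patients on a 64×64×16 grid.  The test suite and
the acceptance script run the full pipeline at 32×32×8 and 48×48×12
respectively (≈1300–3300 gland windows per patient, 27k–66k samples per
cohort, ~900 cancerous) — the package's chosen desk-scale sizes; metrics
saturate identically at the larger defaults.  Sensitivity at the Youden
operating point is the strictest reported number: decision-score scales
vary across LOPO folds on nearly separable data, so the pooled
window-level hit rate is conservative even when AUC ≈ 1.

## Known limitations

* The CHB-DWI "Bayesian" reconstruction is realized as the deterministic
  OLS extrapolation (the two coincide under a flat prior and Gaussian
  log-residuals); no noise-floor correction is applied.
* The CDI density estimator is the simplest consistent choice; dual-stage
  CDI variants are out of scope.
* The mRMR search is over subset sizes along the ranking, not over all
  2^96 subsets.
* DCE imaging, spectroscopy, morphological features and histopathology
  registration are out of scope.
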