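# Methods

This note documents the statistical model behind `bdtaskfmri`, the default
parameters and why they hold, the known limits of the synthetic generator,
and the numerical choices a reviewer should be aware of.

## Problem setting

The package models a leakage-controlled analysis of an emotional Go/NoGo
task-fMRI case-control study: patients in three mood states (remission,
depression, mania) against healthy controls (HC). The analysis chain is

1. synthetic BOLD cohort generation,
2. motion QC and nuisance preprocessing,
3. per-subject (first-level) GLM contrast z-maps,
4. Gaussian-random-field (GRF) cluster correction of group (second-level)
   z-maps,
5. fold-specific "abnormal ROI" time-series features,
6. nested cross-validated classification with bootstrap CIs and Shapley
   (SHAP-style) ROI importance,
7. GRF-corrected brain-behavior association with Benjamini-Hochberg FDR.

The defining constraint is that every data-dependent choice in steps 4-6
(ROI definition, time-series truncation length, feature scaling,
hyperparameters) is refit inside each outer training fold, so held-out
subjects never influence their own feature space.

## Synthetic cohort generator (`simulate`)

Each subject is a 4D grid (default 24x24x24 voxels of 3 mm, 307 volumes at
TR 2 s). A toy atlas partitions the grid interior into rectangular connected
regions (default 12); the one-voxel boundary shell acts as background and
supplies WM/CSF proxy masks. A single event schedule (Go / NoGo / Neutral,
default 20 events per condition, 1 s duration, continuous-time onsets) is
shared by all subjects, as in a fixed task protocol.

Signal model per voxel: baseline 100, plus HRF-convolved condition boxcars
with amplitude `base_activation`, plus, inside `effect_rois`, a Go-amplitude
increment of `effect_size` for patient groups and a per-subject deviation
drawn from N(0, `subject_amp_sd`) for everyone. Noise is AR(1) in time
(coefficient 0.3), spatially smoothed (FWHM 6 mm) and rescaled to
`noise_sd`. Motion traces are smooth drifts plus occasional 0.5 mm spikes
(probability 0.02/volume). Clinical metrics are standard normal scores; a
planted link (region, metric, r) sets the metric to
`r * dev/sd + sqrt(1 - r^2) * noise`, so the population correlation between
the subject's Go-amplitude deviation and the score is exactly `r`.

Known realism limits, by design: boxcar-convolved signals with stationary
Gaussian AR(1) noise (no physiological noise spectra, no spatially varying
smoothness), a rectangular atlas, motion that corrupts the motion *trace*
but not the images (no actual interpolation artifacts), and a common grid in
place of spatial normalization.

## Preprocessing (`preprocess`)

- **Framewise displacement (Jenkinson):** the volume-to-volume rigid
  transform is built from parameter increments `dp = p_t - p_{t-1}`; with
  `M = affine(dp) - I = [A b; 0 0]`, `FD = sqrt(R^2/5 * tr(A'A) + b'b)` with
  R = 80 mm. The increment form is exactly invariant to constant parameter
  offsets and matches the composed-affine definition to second order.
- **Gross-motion exclusion:** any |translation| > 3 mm or |rotation| > 3
  degrees excludes the subject (strict inequality, compared in radians).
- **Scrubbing:** volumes with FD > 0.2 mm get one-hot spike regressors; no
  volumes are deleted, so all subjects keep their full length.
- **Nuisance design:** Friston-24 motion set (p, p^2, lagged p, lagged p^2,
  with p(-1)=0), WM and CSF mean series, a standardized linear trend, and
  the spike columns — 27 + #scrubbed columns. Rank-deficient columns are
  dropped greedily with a warning. Residualization keeps the temporal mean
  (idempotent, units preserved).
- **Band-pass 0.01-0.10 Hz:** frequency-domain hard mask; the DC bin is kept
  so baseline level survives. Applied after nuisance regression.
- **Smoothing:** Gaussian FWHM 4 mm per frame, reflect boundary (conserves
  the frame mean up to boundary effects).

Flagged open question: band-pass *before* the GLM attenuates task harmonics
outside the band; with 1 s events on 2 s TR the fundamental response energy
lies inside 0.01-0.10 Hz for the default schedules, and since all subjects
share the schedule the attenuation is common-mode. WM/CSF series are
extracted before scrubbing; spikes are absorbed by their regressors in the
same fit, so ordering does not change the residuals.

## GLM (`glm`)

First level: OLS per voxel on HRF-convolved condition regressors (canonical
double-gamma; delay parameters 6 s / 16 s, peak:undershoot 6:1, built on a
0.1 s micro-time grid) plus intercept. Contrast t-statistics are converted
to z by the probability-integral transform using log-space tail functions
(`t.logsf` -> `ndtri_exp`), so |t| up to the hundreds maps to finite z. The
six canonical contrasts are Go-NoGo, Go+NoGo, Go-Neutral, NoGo-Neutral, Go,
NoGo. Second level: voxelwise pooled-variance two-sample comparison of
first-level z-maps, sign convention patients minus controls, df = nA+nB-2,
again reported as z.

## GRF cluster correction (`rft`)

Smoothness is estimated from standardized second-level residual maps: the
variance of spatial first differences estimates the roughness `lambda` per
axis, `FWHM = sqrt(4 ln 2 / lambda)`, and RESELs = masked voxels / product
of FWHMs. Clusters form at `u = Phi^-1(1 - voxel_p/2)` separately in each
tail (18-connectivity, faces+edges); a cluster of k voxels gets

    E[m] = R (4 ln 2)^{3/2} (2 pi)^{-2} (u^2 - 1) e^{-u^2/2}
    P(n >= k) = exp(-beta k^{2/3}),  beta = (Gamma(5/2) / E[n])^{2/3}
    p_corrected = 1 - exp(-E[m] P(n >= k))

with `E[n]` the expected cluster size in voxels. A cluster is retained when
`p_corrected < cluster_p / 2` (alpha split across tails) and its extent is
at least `min_extent` (default 10). Self-calibration on 500 null fields of
known smoothness gives an empirical family-wise rate of ~0.02-0.03 at
nominal 0.05 — conservative, as expected from the two-sided split and the
high-threshold approximations.

## Fold-specific features (`features`)

Per outer fold: TRAIN patients vs TRAIN controls second-level z-map -> GRF
mask -> intersect with atlas; regions overlapping by >= 10 voxels are the
fold's abnormal ROIs (K of them; K = 0 skips the fold with a log entry).
Features are ROI-mean time series of the preprocessed BOLD over the
*intersected* voxel sets, truncated to `T_use = min` TRAIN series length,
vectorized ROI-major into `K * T_use` columns, and z-scaled with TRAIN-only
column statistics. The generator keeps Ti constant by default (no volume
deletion), so `T_use` equals the common length; the min rule exists for
cohorts with heterogeneous lengths and is TRAIN-only to avoid leakage. A
TEST series shorter than `T_use` is an error, not a silent pad.

## Classification (`classify`)

Outer 5-fold / inner 3-fold stratified CV. Families: logistic regression,
linear SVM, random forest, XGBoost, Gaussian naive Bayes, each with a small
hyperparameter grid tuned by inner-fold AUC. Out-of-fold TEST predictions
are pooled across outer folds; accuracy, sensitivity, specificity, AUC, F1,
PPV, NPV and FDR (= 100 - PPV) are computed from the pooled confusion
matrix/scores, with NaN for zero denominators. 95% CIs come from 10,000
percentile bootstrap resamples of the pooled subject-level predictions;
one-class resamples are excluded from the AUC distribution and counted.
A pooled-generalization mode classifies all BD states vs HC while sourcing
the ROI definition from one state's TRAIN patients.

## Attribution (`explain`, `shapley`)

Linear models get exact interventional Shapley values
(`w_j (x_j - mean background_j)`); other models a seeded
permutation-sampling explainer whose per-permutation contributions telescope
from the background mean score to the sample score, so local accuracy is
exact for any number of permutations (default 8, background capped at 25
TRAIN rows). Per fold, mean |attribution| per column is summed over each
ROI's columns and normalized to within-fold shares; shares are averaged
over the folds in which an ROI appears and renormalized to sum to 100%.
Renormalization makes shares comparable across fold-varying ROI sets at the
cost of hiding absolute attribution mass, which is reported alongside.

## Clinical associations (`clinical`)

Per (contrast, state, group) block and per metric: voxelwise simple
regression of subject activation (first-level z) on the metric, slope t ->
z (df = n-2), GRF cluster correction as above; surviving clusters get a
cluster-mean activation per subject and a Pearson correlation with the
metric (equal to the standardized regression coefficient), two-sided p.
BH-FDR runs jointly over all (cluster, metric) rows of the block; q < 0.05
is a discovery. Patient and control blocks are always fit separately.

A generator subtlety worth knowing: at large effect sizes the t -> z
transform saturates, so subject z-values stop tracking the underlying
amplitude deviations and planted clinical links become invisible *in z
space* even though they exist in signal space. Association experiments
therefore use moderate effects; this is a property of z-based association
in general, not of this implementation.

## Reproducibility

One master seed drives everything through tagged derivation
(`sha256(f"{seed}:{tag}") mod 2^31`): cohort generation, fold splits,
classifier randomness, bootstrap resampling, Shapley permutations,
background subsampling. Two runs with identical config and seed produce
byte-identical result tables including bootstrap CIs. `RunConfig` hashes
its full parameter set into the run manifest.
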