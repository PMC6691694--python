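# Methods

## Study design being modelled

The pipeline replicates a pretreatment MR-radiomics study of local
recurrence in nasopharyngeal carcinoma: a 140-patient cohort randomly split
4:3 into 80 training and 60 validation patients; 970 radiomic features per
patient (485 per MR modality); per-modality feature selection and Cox
Rad-scores fitted on the training cohort only; a combined radiomic +
clinical Cox model presented as a nomogram; and survival-based validation
(Harrell's C, median-score risk groups with Kaplan–Meier/log-rank,
calibration at 2 and 3 years). Local-recurrence-free survival (LRFS) is the
time in months from the MR exam to observed local recurrence; patients
without recurrence are censored with at least 36 months of follow-up.

## Synthetic cohort generator

Real images are not distributable, so the cohort is synthesized with known
ground truth.

**Geometry.** Volumes are 48×48×16 voxels at (0.9, 0.9, 5.0) mm — the
in-plane resolution of a 23 cm FOV on a 256 matrix and an effective 5 mm
slice spacing (4 mm slices + 1 mm gap). The tumor is an ellipsoid (mean
radius uniform in 6–11 mm, per-axis anisotropy ±20%) with 2–4 attached
spherical lobes, centred with sub-voxel jitter; a generation-time check
rejects tumors that cannot fit.

**Texture.** Each patient carries a latent heterogeneity h ~ U(0, 1). Inside
the mask, intensity = modality base + h · modality texture scale · F + noise,
where F is unit-variance smoothed white noise (Gaussian kernel, σ = 1.5
voxels, i.e. correlation length ≈ 3 voxels) — the cheapest field whose
strength GLCM/GLRLM features can detect. Outside the mask a flat background
level plus the same N(0, 6²) noise. The two modalities use independent
fields and different contrast. What this does *not* emulate: Rician noise,
bias fields, partial-volume effects, motion, real anatomy — so passing
tests demonstrate pipeline correctness and sensitivity to controlled
texture, not clinical performance.

One consequence worth knowing: with fixed-bin-count quantization, in-mask
*variance* rises monotonically with h (ρ ≈ 0.96), but GLCM *contrast*
falls: quantizing between the in-mask min and max normalizes amplitude
away, and as the smooth correlated field outgrows the white noise the
normalized texture becomes smoother. Both are strong monotone readouts of h;
they point in opposite directions.

**Clinical covariates.** Age ~ truncated-normal(46, 10²) on [14, 71];
gender male with p = 103/140; T stage (11, 41, 63, 25)/140; N stage
(11, 44, 73, 12)/140 on an ordinal 1–4 coding; WHO histology III with
p = 137/140, II otherwise; hemoglobin ~ N(135, 13²) g/L and platelets ~
N(235, 55²) ×10⁹/L, chosen so the dichotomized fractions (≥136, ≥238)
match the study population.

**Outcomes.** Event times are exponential with hazard λ₀·exp(βᵀz); the
default ground truth is β_heterogeneity = 2.0 and β_N-stage = 0.2 (a
deliberately realistic, moderate image signal — the C-index of the *true*
linear predictor is ≈ 0.62). Censoring is uniform on [36, 68] months, so
censored times always respect the 36-month minimum follow-up. λ₀ is
calibrated in closed form (P(event) for exponential-vs-uniform censoring is
analytic) to an expected event fraction of 30%. Note that a ~30% event
fraction with a 36-month censoring floor forces the median *observed* time
above 36 months; the median of the observed *event* times lands near 20–30
months. All ground truth (β, per-patient linear predictor, h) is stored
separately and never read by pipeline stages.

## Feature extraction

485 features per modality = 8 shape + 53 intensity × (1 original + 8
wavelet subbands). Naming: `<MOD>_<Shape_name>`, `<MOD>_<class>_<feature>`,
`<MOD>_<subband 1..8>_<class>_<feature>`.

- **First-order (20):** population moments (÷n); skewness g1 = m₃/m₂^1.5 and
  kurtosis m₄/m₂² defined as 0 at zero variance so constant ROIs still give
  complete vectors; entropy/uniformity on a 32-bin equal-width histogram
  (log base 2); percentiles 10/25/75/90, IQR, CV, MAD, RMS, energy.
- **Shape (8):** volume = voxel count × voxel volume; surface area by
  exposed-face counting (exactly reproducible on the digital mask, unlike
  marching cubes); sphericity, compactness 1/2, spherical disproportion,
  surface-to-volume ratio; maximum 3D diameter as the largest pairwise
  distance between surface-voxel centres (convex-hull pruned above 2000
  points).
- **Quantization:** 32 equal-width bins between the in-mask min and max;
  constant ROI ⇒ all level 1; background coded 0. Monotone by construction.
  No resampling: texture runs on the native anisotropic grid with all 13
  unique 3D directions weighted equally.
- **GLCM (22):** distance-1 co-occurrences accumulated symmetrically over
  the 13 directions, summed and normalized; standard Haralick definitions on
  1-based levels, log₂. Degenerate guards: correlation of a zero-variance
  matrix is 1 (a constant ROI is perfectly self-correlated); IMC1/2 are 0
  when marginal entropies vanish.
- **GLRLM (11):** per-direction run-length matrices (background breaks
  runs), the 11 run-emphasis features computed per direction and averaged
  over the 13 directions. Per direction, Σ l·r(i,l) equals the ROI voxel
  count — asserted in tests.
- **Wavelet:** single-level *stationary* (undecimated) Coiflet-1 transform
  so every subband stays on the mask's grid; subband index 1..8 = L/H per
  axis in axis order (1 = LLL … 8 = HHH). Odd axes are symmetrically padded
  and cropped back.

Texture is computed on the ROI bounding box (an exact optimization — every
voxel pair and run lies inside it), which keeps extraction at ~0.1–0.2 s
per patient.

## Feature selection

Binary label: recurrence observed = 1, censored = 0 (defensible because
censored patients have ≥ 36 months of follow-up). Features are z-scored
with training means/SDs. RFE drops one feature per iteration — the smallest
absolute coefficient of an L2 logistic regression (C = 1.0, lbfgs,
tol 1e-6), ties broken by column order — and the reversed elimination order
is the ranking. The subset is chosen by stratified 5-fold CV AUC over top-n
prefixes, ties toward smaller n. The candidate sizes are capped
(`max_subset_size`, default 30): at 80 training patients, CV AUC beyond a
few tens of features is noise, and the cap keeps full runs fast; the
uncapped 1..N sweep is available. Validation rows never reach
standardization, ranking, or subset choice.

## Survival modelling

`CoxPH(data).fit()` returns a results object in the model/results style:
coefficients with SEs/CIs/p-values, the Breslow step-function baseline
cumulative hazard, uncentered linear predictors (the Rad-scores), and
S(t|x) = exp(−Λ₀(t)·exp(βᵀ(x−x̄))). Estimation is delegated to lifelines
(Newton–Raphson, precision 1e-9); with continuous synthetic times there are
no ties, where the Efron and Breslow partial likelihoods coincide. The
modality Rad-score fits use a light ridge (penalizer 0.1) on standardized
features because selected texture features are strongly correlated and can
separate at n = 80; the combined 6-covariate model is unpenalized, with
forced entry of {Rad-score1, Rad-score2, gender, age, HGB, N stage}
(backward elimination at p ≥ 0.05 is available and is used for the
clinical-only comparison model).

Harrell's C counts a pair as usable when censoring leaves the failure order
determinable (earlier time is an event, or tied times with exactly one
event); tied scores credit 0.5; both-event time ties are excluded. The
implementation is vectorized O(n²) and returns the usable-pair count; tests
pin it to a pure-python enumeration oracle exactly and to lifelines on
tie-free data.

Risk groups split at the *training* median of the combined Rad-score;
scores equal to the threshold go to the high-risk group. Calibration groups
patients into quantiles of predicted S(horizon) (4 groups), compares the
group mean prediction with the Kaplan–Meier estimate at the horizon, and
attaches a 200-resample bootstrap percentile CI; horizons beyond follow-up
are truncated with a warning. Note that quantile-grouped calibration does
not punish an *uninformative* model (its predictions collapse to the
marginal survival and match it); the paired calibration test therefore uses
a deliberately biased model, not an omitted-covariate one.

## Nomogram

Each predictor's contribution βᵢxᵢ maps linearly to points anchored at the
value minimizing the contribution over the observed training range (min for
β > 0, max for β < 0); the largest span = 100 points. Total points are an
affine transform of the linear predictor, so the total-points → S(24)/S(36)
lookup through the Breslow baseline reproduces the Cox probabilities
exactly in continuous arithmetic (< 0.01 by test; ≤ 0.02 when the total is
read at integer resolution — per-axis integer rounding adds up to 0.5
points per predictor). Rendering produces one horizontal scale per axis
(points ruler, predictors, total points, one probability axis per horizon):
a 6-predictor model renders 10 axes.

## Numerical/runtime choices

Everything derives from one seed: patient phantoms use per-index spawned
substreams (bit-identical cohorts per seed, independent patients), the
split is a seeded permutation (140 → 80/60 by round(n·4/7)), and CV folds
are seeded. Default problem sizes were chosen so a full 140-patient run
takes ~1 minute on one CPU and the 20-replicate discrimination property
(run at β_heterogeneity = 4 — the strong-signal condition it tests — on a
36×36×16 grid) completes in about ten minutes. Known limitations: no DICOM,
no registration, no multi-level wavelets or GLSZM/NGTDM families, no
time-dependent ROC or competing risks; the published coefficients are
reproduced as frozen constants for scoring, never re-estimated from
synthetic data.
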