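# Methods note

## Imaging model

Volumes are voxel grids with positive finite spacing in mm (RAS axis
convention); NIfTI I/O goes through nibabel, with trailing singleton
dimensions squeezed and non-finite intensities rejected. Region masks are
integer label fields sharing the volume geometry, with labels
1 = intracerebral haemorrhage (ICH), 2 = intraventricular haemorrhage
(IVH), 3 = perihaematomal oedema (PHE). Resampling to a target spacing
uses trilinear interpolation for intensities and per-label nearest /
argmax voting for masks. Region volume is voxel count × voxel volume,
reported in mL.

## Filter bank (13 derived images)

- **Intensities**: the (resampled) input volume.
- **LoG-05 / 15 / 25 / 35**: scale-normalised Laplacian-of-Gaussian at
  σ = 0.5, 1.5, 2.5, 3.5 mm, built separably from explicit kernels with
  reflect boundaries. The 1-D second-derivative taps are corrected to
  exact zero sum, so a constant volume maps to exactly zero despite
  kernel truncation (an off-the-shelf truncated LoG leaves a residual
  ≈ 0.03 on constant input). Responses are multiplied by σ² so blob
  responses are comparable across scales.
- **Wavelet-LLL … HHH**: single-level undecimated separable 3-D wavelet
  transform (coif1), all eight low/high-pass combinations, same shape as
  the input. The decomposition filters are rescaled by 1/√2 per axis so
  the bank is energy-preserving (exact Parseval identity under the
  periodic transform; reflect padding is the default for feature
  extraction).

## Feature catalogue (754 ids, frozen order)

24 shape descriptors on the ICH mask (voxel/mesh volumes, surface area
from a marching-cubes mesh, sphericity, PCA axis lengths, flatness,
elongation, bounding box and convex-hull measures, …), then for each of
the 13 derived images 56 intensity features inside the ICH region:
20 first-order statistics and 36 texture features from four matrix
families — GLCM (9), GLRLM (10), GLSZM (12), NGTDM (5) — computed on a
fixed-bin-number discretisation (32 bins over the in-ROI range). Two
extra volumes (PHE, IVH) complete 24 + 13×56 + 2 = 754.

Texture conventions: 13 unique 3-D direction offsets; GLCM and GLRLM are
computed per direction, normalised, and feature-averaged across
directions; GLSZM zones and NGTDM neighbourhoods use 26-connectivity.
Degenerate guards: constant ROIs give zero contrast/complexity, NGTDM
coarseness is capped at 10⁶, empty-direction matrices are skipped in the
average. The binary ROI is smoothed with a σ = 1 voxel Gaussian before
marching-cubes meshing (raw fallback if the smoothed field has no
crossing); raw staircase meshes overestimate surface area and push
digital-ball sphericity down to ≈ 0.92, while the smoothed mesh sits in
[0.97, 1.005].

## Harmonisation (ComBat)

Slice thickness defines three batches: < 2 mm, [2, 4) mm, ≥ 4 mm.
Parametric empirical-Bayes location–scale ComBat: features are
standardised against a covariate-adjusted grand model (optional
biological covariates, e.g. age and gender, are preserved), per-batch
location and scale parameters are shrunk toward their across-feature
prior moments, and the batch effect is removed on the original scale.
Numerical choices:

- Per-batch scale estimates use the population variance (ddof = 0), which
  makes single-batch harmonisation the exact identity.
- A degenerate across-feature scale prior (zero spread) collapses to a
  point mass at its mean, keeping the EB iteration finite.
- Harmonisation is *approximately* idempotent: a second pass changes
  values by order √(2/n) × shrink-weight (≈ 0.02–0.04 for typical n),
  not machine precision — this is inherent to EB shrinkage.
- Parameters fitted on training data are serialised to JSON and applied
  unchanged to held-out data; unseen batch levels are an error.

Batch mixing is quantified by a silhouette-style score on standardised
features (≈ 0 for well-mixed batches, → 1 for separated clusters).

## Feature selection

Iterative correlation filter (find-correlation convention): repeatedly
locate the feature pair with the largest |Pearson r| above the cutoff
(default 0.9) and drop the member with the larger mean absolute
correlation to the remaining features; ties drop the later column.
Zero-variance columns are dropped up front with a warning. The filter is
fitted on training data only.

## Elastic-net logistic model

Objective: mean logistic log-loss + λ(α‖β‖₁ + (1−α)/2‖β‖₂²) on
standardised features (means/SDs stored in the model for exact
application to new data). Solved by FISTA proximal gradient with
adaptive restart and warm starts along a descending λ path;
λ_max = ‖Xᵀ(y−ȳ)‖∞/n (divided by max(α, 10⁻³) for small α, the glmnet
convention). Model selection: stratified k-fold cross-validation (k = 10
default) over α ∈ {0, 0.1, …, 1} × a geometric λ path (100 values over
4 decades by default; tests and the acceptance script use 30 values over
3 decades for runtime), maximising mean validation AUC with ties broken
toward larger λ then smaller α.

Every per-α path is prepended with a **null anchor** λ = λ_max×10⁶ so the
intercept-only model (constant scores, CV AUC exactly 0.5) is always a
candidate. Without it, fold-level λ_max exceeds the global λ_max, every
grid cell is overfit on pure-noise data, and the rank-based CV AUC of the
selected model is systematically pessimistic (≈ 0.38); with the anchor the
null model wins on noise and CV AUC stays honest at ≈ 0.5.

Variable importance is reported as 100·|b_j| / Σ|b_k| on standardised
coefficients, intercept excluded.

## Outcomes and evaluation

- Haematoma expansion: follow-up minus baseline ICH volume > 6 mL **or**
  > 33% of baseline (strict inequalities; zero baseline is an error).
- Poor functional outcome: day-90 modified Rankin Scale 4–6.
- Ultra-early haematoma growth: baseline volume / onset-to-scan hours.
- Train/test split: 70/30, age- and gender-matched within
  gender × age-quintile × outcome strata with probabilistic rounding;
  accepted when rank-sum (age) and chi-square (gender) tests both give
  p > 0.05.
- AUC via the tie-corrected Mann–Whitney statistic with DeLong 95% CI;
  operating point by the Youden index (score ≥ threshold, lowest
  threshold on ties); sensitivity/specificity/PPV/NPV/prevalence with
  Wald 95% CIs (z = 1.959963984540054) on each metric's own denominator;
  F-score profiles (F0.5/F1/F2) over all candidate thresholds.

## Synthetic data

The phantom generator builds ellipsoidal head CTs on a 1 mm grid
(brain 30 HU, haematoma 65 HU, oedema 18 HU, CSF 8 HU, plus per-tissue
Gaussian noise), then slab-averages to 1/3/5 mm slices with
majority-vote label downsampling. The feature-level cohort generator
produces Gaussian feature tables (optional high-correlation block),
clinical covariates matching the target population (age ~ N(69, 13), 56%
male, 1:1 allocation), and outcomes from a known model: log-normal
haematoma growth with a feature-dependent mean (labelled by the
6 mL/33% rule — the OR of the two criteria binds at the smaller relative
threshold) and Bernoulli-logistic poor outcome, with intercepts
calibrated by bisection to the target prevalences (0.27, 0.50).
Limitations: phantom haematomas are spherical and texture-free beyond
noise, and the feature-level generator has no spatial structure — it
validates statistical machinery, not biological realism.

## Validation strategy

Each numerical component is tested against an independent oracle:
texture features against naive loop re-implementations of all four
matrix families; the correlation filter against a one-pair-at-a-time
brute force; AUC against explicit pair counting; the Youden threshold
against exhaustive search; the solver against an unpenalised BFGS
maximum-likelihood fit and scikit-learn's saga elastic-net; ComBat
against R `sva::ComBat` (loose tolerance — formulation details differ);
plus calibration, determinism, serialisation round-trip, and train/test
leakage discipline checks throughout.
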