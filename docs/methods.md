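# Methods

## Similarity model

A subject's input is one spatially normalized 3D metabolic volume — one
value per voxel, e.g. the temporal average of a dynamic FDG-PET series.
For a seed region *i* and a comparison region *j*, each summarized by the
mean *m* and sample standard deviation *σ* (n−1 denominator) of its voxel
intensities, the connectivity is

S = exp( −(mᵢ − mⱼ)² / (2 (σᵢ² + σⱼ²)) ).

Properties relied on throughout: S ∈ (0, 1] (floating-point underflow can
reach exactly 0 for extreme separations); S = 1 iff the means coincide;
symmetry in (i, j); strict monotone decay in |mᵢ − mⱼ|; invariance to
adding a constant to the whole volume (means shift together, σ unchanged)
*and* to multiplying it by c > 0 (c cancels between (cΔm)² and c²σ²), so S
is unaffected by global affine intensity changes — only shape differences
between regional distributions matter. A proportional global-mean scaling
switch exists on the searchlight call (it standardizes the m/σ metadata
recorded per subject) but, by this invariance, it cannot change any S
value; it is off by default. If both σ vanish (constant regions) the limit value is used —
1 for equal means, 0 otherwise — and a `DegenerateVarianceWarning` is
emitted.

The searchlight engine evaluates S between the seed and a sphere centred
on every brain-mask voxel. Sphere membership is by Euclidean distance
between voxel centres in world millimetres (anisotropic voxels handled via
the affine), intersected with the brain mask, centre included. Defaults:

- `radius_mm = 6` (two voxels on a 3 mm grid). The radius materially
  affects results and is therefore explicit in the API and recorded in the
  output sidecar.
- `min_voxels = 2`: a sphere must support a standard deviation; smaller
  in-mask spheres leave the voxel undefined (NaN) rather than invoking the
  degenerate limit.
- Seed-overlapping centres are computed like any other voxel; the seed
  mask travels with the map and cluster reports flag overlap, which keeps
  the choice auditable instead of silently dropping voxels.
- Brain mask, when not supplied: voxels positive in ≥ 90% of subjects — a
  deterministic, recorded rule.

Statistics are **spatial** (across voxels of the single averaged map), not
temporal; this is what makes the index a *covariance* connectivity rather
than a time-series correlation.

## Group model and inference

Per-subject similarity maps are stacked and fit voxelwise by OLS on the
design (intercept, score, age, sex, mean framewise displacement);
contrast on the score column, t on df = n − p (27 subjects, 5 columns →
df = 22). Voxels missing in any subject are excluded listwise, keeping df
constant across the map. Two-level string covariates are coded 0/1 by
sorted level order (female = 0, male = 1), and the mapping is stored on
the design. Zero-residual voxels (similarity exactly linear in the
design) would give infinite t; |t| is capped at 1e6 and flagged.

Cluster inference: supra-threshold voxels at the Student quantile for the
cluster-forming p (default 0.001, one-sided in the tested direction —
the default contrast is one-sided *negative*, matching the hypothesis of
symptom-related connectivity decreases; two-sided splits the tail mass)
are grouped by 18-connectivity (6 and 26 selectable). Cluster-extent FWE
p-values come from a Freedman–Lane permutation scheme: the maps are
regressed on the nuisance-only design, residual rows are permuted by a
fresh draw from the seeded generator each iteration, the nuisance fit is
added back, the full model is refit, and the maximum cluster size at the
same forming threshold is recorded; then
p_FWE = (1 + #{max size ≥ observed}) / (n_perm + 1), never exactly zero.
Permutation was chosen over parametric random-field cluster inference
because it is exact under exchangeability and needs no smoothness
estimation; the cluster table labels the method. Within-cluster peaks are
the largest |t|, ties broken by lexicographically smallest voxel index,
for full determinism. Tables sort by p_FWE, then descending size.

## Synthetic cohorts

Each volume is `baseline (100) + smoothed noise + target offset`:

- **Noise**: white Gaussian noise filtered with a Gaussian kernel
  (FWHM = σ·2√(2 ln 2)) using periodic boundaries, so the field is
  stationary and the renormalization to a per-voxel SD of exactly
  `noise_sd` is exact (`reflect` boundaries inflate edge variance).
  Default `noise_sd = 5`, i.e. 5% of baseline — a realistic regional
  coefficient of variation for smoothed uptake images.
- **Coupling**: inside the target sphere the volume gains
  `coupling_slope × score`. The offset is anchored at the score floor of
  zero (symptom scales are non-negative) rather than at the cohort mean:
  the similarity depends on |Δm|, so a mean-centred offset would peak at
  the mean score and fall on both sides, destroying monotonicity; the
  anchored form makes seed–target similarity strictly monotone in the
  score, and slope 0 is an exact null.
- **Participants**: scores truncated-normal at zero (mean 9.1, sd 8.3 —
  pooled moments of the emulated cohort's printed per-sex summaries);
  ages uniform 18–23; sex Bernoulli with P(female) = 20/27, redrawn in
  the degenerate all-one-level case so sex is usable as a covariate;
  mean framewise displacement lognormal with median 0.15 mm. Per-subject
  noise streams are spawned from one seed sequence, so cohorts are fully
  reproducible and order-independent.

Default geometry and effect size (the conditions used by the validation
suite): 16³ grid of 3 mm voxels, seed sphere radius 6 mm at
(−10.5, 0, 0) mm, target sphere radius 9 mm at (10.5, 0, 0) mm,
smoothness 4 mm FWHM, slope −1.0. Two of these deserve justification:

- **Smoothness 4 mm** is below typical PET effective smoothness. On a
  16³ grid a 6 mm-FWHM field leaves only ~1–2 independent noise samples
  inside a 33-voxel sphere, so regional means fluctuate with nearly the
  full noise SD and the similarity statistic is mean-noise dominated —
  an artefact of the scaled-down grid, not of the method, whose real
  inputs have hundreds to thousands of voxels per region. 4 mm restores
  several independent samples per region while keeping fields smooth.
- **Slope −1.0** plants a voxelwise score–similarity correlation of
  about −0.85 at the target centre (about −0.69 under 6 mm smoothness),
  i.e. a genuinely strong effect of the magnitude such studies report
  for their peak voxels (t ≈ −4.5 at df 22 corresponds to |r| ≈ 0.69).
  Larger |slope| saturates S near 0 for most subjects and weakens, not
  strengthens, the observable correlation.

What the generator does **not** emulate: PET acquisition physics, tracer
kinetics, motion, anatomical structure (the baseline is flat), spatially
varying noise, and between-region covariance beyond the planted effect.
Passing tests therefore demonstrate statistical correctness of the
pipeline (calibration, recovery, contracts) on idealized inputs — not
that any particular real-data finding is reproducible.

## Validation conditions and results computed

- **Null calibration**: 200 cohorts with slope 0 (n = 27, 16³ grid,
  199 permutations, fixed seeds); the family-wise rejection rate at
  nominal 0.05 must fall inside the 95% binomial band [0.02, 0.09], and
  p-values must be valid (P(p ≤ α) ≤ α plus binomial error) at α = 0.01
  and 0.05.
- **Effect recovery**: 20 cohorts at the default strong coupling; the
  most significant cluster must overlap the planted target with
  Dice > 0.3 in ≥ 18 of 20 replicates, with a negative fitted score
  effect at the true peak in all.
- **Oracle equivalence**: the vectorized searchlight matches a naive
  per-voxel sphere-enumeration recomputation to 1e−12 on a 12³ volume;
  the voxelwise GLM matches explicit normal equations to 1e−10.
- **Demographic statistics**: chi-square (no continuity correction;
  the corrected variant gives ≈ 0.021 instead of the printed 0.012) and
  pooled-variance t (Welch is far off the printed values) reproduce the
  emulated cohort's printed p-values to 3 decimals. The n = 7 group means
  are first un-rounded to exact sevenths (a 2-decimal mean of 7
  observations is an exact multiple of 1/7); from the literally rounded
  means, the age p-value comes out 0.119 rather than 0.118.

These problem sizes (16³ grids, 199–499 permutations) were chosen so the
full validation suite runs in a couple of minutes on one CPU while the
permutation counts still resolve p-values at the granularity the checks
need; all quantities are recomputed at run time by `scripts/acceptance.py`.

## Known limitations

- Cluster-extent inference assumes exchangeability of nuisance-adjusted
  residuals across subjects; heteroscedastic cohorts would need a
  different scheme.
- The similarity index ignores global affine intensity changes entirely;
  conversely it cannot detect effects expressed purely as global scaling.
- No spatial resampling: all inputs must share one grid; mismatches are
  errors by design.
- The searchlight radius is not estimated from data; results should be
  reported together with the radius used.
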