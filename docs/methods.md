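# Methods

## Measurement model

The package quantifies diffusion in and around a breast tumor on a
co-registered ADC map (units ×10⁻³ mm²/s throughout). The geometry is
defined entirely by the binary tumor segmentation after resampling to
isotropic voxels:

- **Resampling.** Volumes are interpolated tri-linearly, masks by nearest
  neighbor, onto a grid with the same origin and voxel-center extent at
  `target_mm` (default 1.0 mm) spacing. Voxel indices are 0-based and
  physical coordinates are voxel-center based, so a linear intensity ramp
  resamples exactly onto itself.
- **Intratumoral VOI.** The tumor mask is eroded by one voxel with the
  6-connected (face-adjacent) structuring element. At 1 mm isotropic spacing
  this removes exactly the 1 mm boundary layer; the 26-connected element
  would erode ~√3 mm at corners. If erosion empties a degenerate tumor, the
  original mask is retained with a warning rather than failing, so
  cohort-scale runs keep going. The intratumoral mean ADC uses the eroded
  VOI; tumor volume (an anatomical quantity) uses the un-eroded mask.
- **Distance field and shells.** For every voxel outside the tumor the
  Euclidean distance (in mm, honoring anisotropic spacing) to the nearest
  tumor voxel is computed; voxels inside get 0. Shells are the half-open
  bands (0, 2], (2, 5], (5, 10] mm of this field, outside the tumor, inside
  the grid, and outside an optional exclusion mask. Half-open intervals make
  the printed ranges 0–2 / 2–5 / 5–10 tile without overlap. Distances are
  measured from the **original** (un-eroded) tumor surface: erosion exists
  to keep tumor signal out of the tumor mean, not to shift the anatomical
  shells inward (the alternative reading would translate every shell 1 mm
  toward the tumor). A shell is flagged `clipped` when tissue at its
  distances falls outside the grid, and `empty` when no voxel survives;
  empty compartments yield missing metrics, never zeros.
- **Reference VOI.** The eroded tumor VOI reflected across the mid-plane of
  the left–right axis (volumes are reoriented to a canonical RAS-like axis
  order on load so this plane is well defined). The reflection preserves
  voxel count and craniocaudal extent, realizing a contralateral VOI of
  equivalent size at the same anatomical level; a user-supplied reference
  mask overrides it (e.g. for midline lesions, where the mirror overlaps the
  tumor and is rejected).
- **Metrics.** Mean ADC per compartment by plain voxel-wise averaging
  (missing voxels excluded from numerator and count); rADC = compartment
  mean / reference mean; per-patient ratios tumor mean / shell mean. Ratios
  are formed per subject *before* any cohort summarization, so a cohort
  median of ratios is generally not the ratio of cohort medians.

### Known discretization behavior

The distance field measures center-to-center distance to the nearest tumor
voxel. For a digital sphere this places the effective tumor surface
~0.3 mm inside the continuum sphere, so thin bands carry a systematic
volume bias: for R = 10 mm at 1 mm spacing the (0, 2] band holds ~16% fewer
voxels than the continuum value 4π/3((R+2)³−R³), while the (2, 5] and
(5, 10] bands agree within ~3%. Alternative metrics (distance to voxel
cubes, or a half-voxel offset) overshoot by similar amounts in the other
direction. The bias affects absolute shell *volumes*, not shell *means* on
data whose compartments follow the same voxel geometry, and it is shared by
any margin-growing implementation that thresholds a voxelized distance map.

## Statistics

- **Group comparisons** default to the nonparametric branch: two-sided
  Mann–Whitney U (exact enumeration when both groups have n ≤ 8 and no
  cross-group ties, otherwise the normal approximation with continuity
  correction and mid-rank ties) and Kruskal–Wallis with tie correction.
  Pairwise post-hoc Mann–Whitney tests run only when the omnibus p < 0.05
  and are Bonferroni-adjusted within that family; no global correction is
  applied across metrics. A Welch t-test is available as a parametric
  opt-in. All-identical inputs yield H = 0, p = 1 by convention.
- **Correlation** is mid-rank Spearman; constant vectors are an error
  rather than NaN.
- **ICC** uses the two-way random-effects, absolute-agreement,
  single-measurement model ICC(2,1) — the strictest common choice for
  interobserver agreement of continuous ADC measurements; computed via
  pingouin and cross-checked in the test suite against the closed-form
  mean-squares decomposition.
- **ROC.** Scores carry an explicit rule direction; internally they are
  oriented so higher = more likely positive and cutoffs are mapped back for
  reporting, avoiding silent AUC < 0.5 ambiguity. The AUC is the
  Mann–Whitney estimator with tie weight ½ (identical to the sweep
  trapezoid). DeLong placement values give the AUC variance, the Wald 95%
  CI truncated to [0, 1], the two-sided test against 0.5, and the paired
  covariance for comparing two markers on the same subjects. Degenerate
  cases (AUC exactly 0/1 with zero variance, or fully tied scores) collapse
  the CI and are flagged.
- **Operating points.** The Youden cutoff maximizes J = sens + spec − 1
  with ties broken toward higher specificity, then lower cutoff.
  Fixed-specificity (or -sensitivity) points report the *achieved* empirical
  point with the smallest specificity ≥ target — never an interpolated
  rate. Confusion counts are reconstructed from printed rates by half-up
  rounding of sens·n₊ and spec·n₋, which uniquely reproduces every mutually
  consistent PPV/NPV cell for the 27/41 split; printed accuracy values that
  contradict their own sensitivity/specificity pair are thereby detectable.
- **Logistic models** are maximum-likelihood fits (statsmodels). ADC-scale
  predictors are rescaled so odds ratios read per +0.1 unit; tumor volume
  enters as log₂(volume) so its OR is per doubling. Perfect separation is
  detected (non-convergence or diverging coefficients) and raised, not
  reported as a huge OR.
- **Internal validation** of a single-marker rule runs stratified 5-fold CV
  repeated 200 times (fold AUCs averaged per repeat; the result records the
  repeat-level mean/sd and, separately, the fold-level sd, which is several
  times larger at n ≈ 68 — summaries quoting ±0.13-scale dispersions are
  fold-level) and a 2000-iteration unstratified bootstrap. Optimism is the
  mean of (AUC on resample − AUC of the resample-derived rule on the
  original data); for a fixed marker the rule never changes, so optimism is
  ≈ 0 and the corrected AUC tracks the apparent one — refitted models would
  show genuine optimism. The Youden cutoff is recomputed on every resample
  for cutoff-stability reporting. Resamples that lose a class are redrawn.
  All streams derive deterministically from one base seed, so results are
  bit-reproducible.
- **Frozen thresholds** from a derivation cohort are applied to new cohorts
  without re-optimization, yielding the full confusion summary at the fixed
  cutoff.

## Synthetic data

- **Phantom.** A bilateral 1 mm grid (default 96×64×64) with an ellipsoidal
  tumor (default: 7 mm-radius sphere) on one side. Compartment bands are the
  EDT level sets of the analytically voxelized tumor — the identical
  geometry the pipeline measures — so with zero noise the extracted metrics
  equal the configured compartment levels exactly; that is what makes the
  phantom usable as ground truth. Default levels follow the cohort medians
  for invasive breast cancer: tumor 0.88, shells 1.52 / 1.42 / 1.57
  (deliberately non-monotonic: the intermediate 2–5 mm zone is the most
  diffusion-restricted), reference 1.55. The default noise is 0 because the
  phantom's role is analytic verification; additive Gaussian noise and
  high-ADC adipose blocks (which populate the exclusion mask) are opt-in.
  The phantom does **not** emulate textured fibroglandular tissue, Rician
  noise, EPI distortion, or partial-volume mixing, so passing phantom tests
  demonstrates geometric and arithmetic correctness, not robustness to
  real-data artifacts.
- **Cohorts.** The five base ADC compartments per patient are log-normal,
  parameterized by median and IQR (the natural summary for positive,
  right-skewed metrics) with nodal-status-specific anchors; rADC and ratio
  columns are *computed* from the base compartments, so the per-patient
  metric identities hold exactly in every generated table. Shell and
  reference compartments share a parenchymal latent factor (ρ = 0.5 on the
  log scale — a modeling choice, since within-patient cross-compartment
  dispersion is not observable from printed summaries); the tumor
  compartment has an independent cellularity latent that also drives Ki-67,
  grade, and LVI, which is why intratumoral ADC and the ratio metrics
  correlate negatively with proliferation markers while pure shell ADCs do
  not. Because the printed group medians/IQRs understate the within-patient
  tumor–shell coupling, the induced ratio-metric separation (AUC ≈ 0.8) is
  stronger than observed in real cohorts (≈ 0.72); markers at a *calibrated*
  AUC are generated instead from the binormal model, Δ = √2·Φ⁻¹(AUC), which
  is the path used for AUC-recovery checks. The default cohort is 68
  patients with exactly 27 outcome-positive (fixed-count mode; Bernoulli
  draws are opt-in), LVI prevalence 0.25, subtype mix 19/65/9/7%, and grade
  mix 32/52/16%.

## Problem sizes and numerical choices

Verification suites run at the study's scale: cohorts of n = 68 with 27
positives; 500 replicates for AUC-recovery means; 1000 replicates for the
DeLong size check; 12 null cohorts for the corrected-AUC mean (a single
null draw has AUC sd ≈ 0.085 at 27 + 41, so per-draw bands tighter than
~3σ would be noise assertions); geometry oracles on grids ≤ 45³ where the
O(N·M) brute force is exact and fast. Grid-matching tolerance is 10⁻³ mm
on spacing and origin; metric identities are asserted to 10⁻⁹; oracle
equivalences to 10⁻¹².

## Limitations

- ADC maps are inputs: no DICOM handling, no multi-b-value fitting, no
  registration (sequences are assumed co-registered).
- Breast/skin/pectoral segmentation is not computed; exclusion masks are
  caller-supplied.
- Only the compartment mean is extracted — no histogram, texture, or
  kurtosis/IVIM features.
- The mirrored reference VOI assumes roughly symmetric bilateral anatomy;
  midline lesions require a manual reference mask.
- Survival analysis and external multicenter validation are out of scope;
  frozen-threshold evaluation on a new cohort is the supported
  generalizability check.
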