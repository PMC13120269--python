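# shelladc

Quantitative analysis of the peritumoral microenvironment in breast MRI from
apparent diffusion coefficient (ADC) maps.

In invasive breast cancer, the tissue immediately surrounding a tumor is not a
passive backdrop: stromal remodeling, lymphatic obstruction, and
microvascular changes near the invasion front carry information about
aggressiveness and nodal spread. `shelladc` turns a 3D ADC map
(×10⁻³ mm²/s) plus a tumor segmentation into a standardized set of
per-patient diffusion metrics, and provides the decision-oriented statistics
needed to evaluate those metrics against clinical outcomes such as axillary
lymph node status (pN), lymphovascular invasion, molecular subtype, grade,
and Ki-67.

The measurement pipeline:

1. **Resampling** — volume and masks to 1 mm isotropic voxels (tri-linear /
   nearest neighbor).
2. **Intratumoral VOI** — one-voxel 6-connected erosion of the tumor mask,
   so shell measurements are not contaminated by tumor signal (tumor volume
   is still reported for the un-eroded mask).
3. **Concentric peritumoral shells** — the Euclidean distance field from
   the (un-eroded) tumor surface slices the surroundings into half-open
   bands at (0, 2], (2, 5], and (5, 10] mm, excluding skin/muscle/adipose
   voxels given as an optional exclusion mask.
4. **Contralateral reference VOI** — the tumor VOI mirrored across the
   midsagittal plane (identical voxel count, same craniocaudal level), or a
   manually supplied reference mask.
5. **Metrics** — mean ADC per compartment; normalized values
   rADC<sub>x</sub> = ADC<sub>x</sub> / ADC<sub>ref</sub>; per-patient
   intratumoral-to-peritumoral ratios
   ADC<sub>tumor</sub> / ADC<sub>shell-k</sub>.

The statistics layer covers Mann–Whitney / Kruskal–Wallis group comparisons
with Bonferroni post-hoc families, Spearman correlation, ICC(2,1)
interobserver agreement, empirical ROC curves with an explicit rule
direction ("low predicts positive" for ratio metrics), DeLong variance for
AUC confidence intervals and paired curve comparison, Youden and
fixed-sensitivity/specificity operating points, confusion-matrix
reconstruction from printed rates, logistic models with interpretable
scalings (per +0.1 unit; tumor volume per doubling), repeated stratified
5-fold cross-validation, bootstrap optimism correction, and frozen-threshold
evaluation on independent cohorts.

A synthetic-data module generates bilateral ADC phantoms with analytic
ground-truth geometry and patient-level cohorts with realistic group
structure, so the entire pipeline is testable without any patient data.

## Worked example

```python
import shelladc as sa
from shelladc.synthetic_data import PhantomSpec, CohortSimSpec

# a noisy bilateral phantom: tumor 0.88, shells 1.52 / 1.42 / 1.57,
# reference 1.55 (x1e-3 mm^2/s), Gaussian noise sd 0.1
vol, tumor, excl, truth = sa.generate_phantom(PhantomSpec(noise_sd=0.1, seed=1))
metrics, shells = sa.process_case(vol, tumor)
print(metrics.adc_tumor, metrics.adc_shell1, metrics.ratio_shell1)
# 0.8769 1.5188 0.5774

# a simulated 68-patient cohort (27 pN+) and the ROC analysis of the
# intratumoral/peritumoral ratio for the innermost shell
t = sa.generate_cohort(CohortSimSpec(seed=1))
curve = sa.roc(t["ratio_shell1"], t["pN_status"], "low_predicts_positive")
auc = sa.delong_auc_inference(curve)
pt = sa.youden_cutoff(curve)
val = sa.validate_internal(t["ratio_shell1"].to_numpy(),
                           t["pN_status"].to_numpy(),
                           "low_predicts_positive", seed=1)
```

which prints, for seed 1:

```
AUC 0.717 (95% CI 0.595-0.839), p vs 0.5 = 0.00049
Youden cutoff 0.603: sens 0.889, spec 0.561, acc 0.691
cv mean AUC 0.718 (sd 0.018); corrected AUC 0.718 (95% CI 0.586-0.832)
cutoff bootstrap median 0.593, IQR 0.560-0.603
```

Read: a low tumor-to-shell ratio (restricted tumor diffusion relative to its
immediate 0–2 mm surroundings) predicts nodal positivity with an AUC around
0.72; the cross-validated and optimism-corrected AUCs agree with the
apparent one because a single fixed marker has nothing to overfit, and the
Youden cutoff is stable across bootstrap resamples.

The same operations are available from a shell:

```sh
shelladc simulate phantom --seed 1 --out-dir phantom/
shelladc shells  --adc phantom/adc.nii.gz --tumor-mask phantom/tumor.nii.gz --out-dir vois/
shelladc metrics --adc phantom/adc.nii.gz --tumor-mask phantom/tumor.nii.gz --out metrics.csv
shelladc simulate cohort --seed 1 --out cohort.csv
shelladc analyze roc --cohort cohort.csv --metric ratio_shell1 --direction low \
    --operating-points youden,spec80,spec85,sens80 --out roc.json
```

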