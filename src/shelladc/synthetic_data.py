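"""Synthetic ADC phantoms and patient cohorts with analytic ground truth.

The phantom emulates the measurement setting of the pipeline: a bilateral
1 mm-isotropic grid holding an ellipsoidal tumor on one side, concentric
distance bands around it at the compartment ADC levels observed for invasive
breast cancer (tumor ~0.88, 0-2 mm shell ~1.52, 2-5 mm shell ~1.42, 5-10 mm
shell ~1.57, reference fibroglandular tissue ~1.55, all x1e-3 mm^2/s — note
the deliberately non-monotonic shell gradient), plus optional high-ADC
adipose blocks to exercise the exclusion-mask path.  For a spherical tumor
the compartment boundaries are closed-form level sets of the radial distance;
for general ellipsoids the truth distance field falls back to the Euclidean
distance transform of the analytically voxelized tumor.

The cohort generator draws the five base ADC compartments per patient from
log-normal distributions parameterized by median and IQR (the natural
summary for positive, right-skewed ADC metrics), with outcome-group-specific
locations; normalized (rADC) and ratio columns are then *computed* from the
base compartments so the per-patient metric identities hold exactly.  A
tumor-cellularity latent couples Ki-67, grade, and LVI to the intratumoral
(and hence ratio) metrics while leaving shell ADCs uncorrelated.  Markers can
alternatively be calibrated to a target AUC via the binormal shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import GeometryError, ParameterError
from .shell_geometry import ShellSet, ShellSpec, erode_one_voxel
from .volume_io import SUBTYPES, BinaryMask, ImageVolume, validate_cohort

# compartment ADC levels (x1e-3 mm^2/s): cohort medians for invasive breast
# cancer; the shell gradient is non-monotonic (0-2 mm > 2-5 mm < 5-10 mm)
DEFAULT_COMPARTMENTS = {
    "tumor": 0.88,
    "shell1": 1.52,
    "shell2": 1.42,
    "shell3": 1.57,
    "reference": 1.55,
}

#: z-spread of the quartiles of a normal distribution (Phi^-1(0.75) * 2)
_IQR_Z = 2 * stats.norm.ppf(0.75)


@dataclass
class PhantomSpec:
    """Geometry and compartment levels of a bilateral ADC phantom."""

    shape: tuple[int, int, int] = (96, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    center_mm: tuple[float, float, float] | None = None   # default: right side
    semi_axes_mm: tuple[float, float, float] = (7.0, 7.0, 7.0)
    tumor_adc: float = DEFAULT_COMPARTMENTS["tumor"]
    shell_bands: tuple[tuple[float, float, float], ...] = (
        (0.0, 2.0, DEFAULT_COMPARTMENTS["shell1"]),
        (2.0, 5.0, DEFAULT_COMPARTMENTS["shell2"]),
        (5.0, 10.0, DEFAULT_COMPARTMENTS["shell3"]),
    )
    background_adc: float = DEFAULT_COMPARTMENTS["reference"]
    noise_sd: float = 0.0
    adipose_blocks: tuple[tuple[tuple[int, int], tuple[int, int], tuple[int, int]], ...] = ()
    adipose_adc: float = 2.2
    allow_clipping: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ParameterError("semi-axes must be positive")
        if self.tumor_adc <= 0 or self.background_adc <= 0:
            raise ParameterError("compartment ADC levels must be positive")
        prev = 0.0
        for inner, outer, value in self.shell_bands:
            if inner != prev or outer <= inner or value <= 0:
                raise ParameterError("shell bands must tile (0, max] without overlap")
            prev = outer


def _phantom_distance(spec: PhantomSpec, center):
    """Ground-truth tumor membership and outside distance field.

    The tumor is voxelized analytically from the ellipsoid inequality; the
    compartment bands are the level sets of the Euclidean distance to the
    nearest tumor voxel (the same geometry the measurement pipeline uses, so
    zero-noise recovery is exact by construction, and independently checkable
    against a brute-force nearest-voxel scan).
    """
    grids = np.meshgrid(
        *(np.arange(n) * s for n, s in zip(spec.shape, spec.spacing)),
        indexing="ij",
    )
    q = sum(((g - c0) / ax) ** 2
            for g, c0, ax in zip(grids, center, spec.semi_axes_mm))
    inside = q <= 1.0
    d = ndimage.distance_transform_edt(~inside, sampling=spec.spacing)
    return inside, d


def generate_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[ImageVolume, BinaryMask, BinaryMask, ShellSet]:
    """Build (volume, tumor mask, exclusion mask, ground-truth ShellSet).

    Voxel values are the compartment level of the voxel's ground-truth band
    plus additive Gaussian noise; the contralateral half of the grid is
    homogeneous background so the mirrored reference VOI is exact.
    """
    spec = spec or PhantomSpec()
    outer_max = max(b[1] for b in spec.shell_bands)
    if spec.center_mm is None:
        cx = (spec.shape[0] - 1) * spec.spacing[0] * 0.75
        cy = (spec.shape[1] - 1) * spec.spacing[1] / 2
        cz = (spec.shape[2] - 1) * spec.spacing[2] / 2
        center = (cx, cy, cz)
    else:
        center = spec.center_mm
    extent = tuple((n - 1) * s for n, s in zip(spec.shape, spec.spacing))
    margin = outer_max
    for c0, ax, ext in zip(center, spec.semi_axes_mm, extent):
        if not spec.allow_clipping and (c0 - ax < margin or c0 + ax > ext - margin):
            raise GeometryError(
                f"tumor does not fit the grid with a {margin} mm margin; "
                "set allow_clipping to override"
            )

    inside, d = _phantom_distance(spec, center)
    tumor = BinaryMask(inside, spec.spacing, role="tumor")
    if tumor.is_empty:
        raise GeometryError("tumor ellipsoid contains no voxel centers")

    values = np.full(spec.shape, spec.background_adc, dtype=float)
    values[tumor.data] = spec.tumor_adc
    truth_shells = []
    for inner, outer, level in spec.shell_bands:
        band = (d > inner) & (d <= outer)
        values[band] = level
        truth_shells.append(BinaryMask(band, spec.spacing, role="shell"))

    excl = np.zeros(spec.shape, dtype=bool)
    for (x0, x1), (y0, y1), (z0, z1) in spec.adipose_blocks:
        values[x0:x1, y0:y1, z0:z1] = spec.adipose_adc
        excl[x0:x1, y0:y1, z0:z1] = True
    exclusion = BinaryMask(excl, spec.spacing, role="exclusion")
    for s in truth_shells:  # exclusion takes priority in the ground truth too
        s.data &= ~excl

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    volume = ImageVolume(values, spec.spacing)
    eroded = erode_one_voxel(tumor)
    mirrored = BinaryMask(eroded.data[::-1, :, :].copy(), spec.spacing,
                          role="reference")
    dist_field = ImageVolume(d, spec.spacing)
    specs = [ShellSpec(b[0], b[1]) for b in spec.shell_bands]
    truth = ShellSet(
        tumor_voi=eroded,
        tumor_mask=tumor,
        shells=truth_shells,
        specs=specs,
        distance_field=dist_field,
        reference_voi=mirrored,
        clipped=[False] * len(specs),
        empty=[not s.data.any() for s in truth_shells],
    )
    return volume, tumor, exclusion, truth


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def binormal_shift(target_auc: float) -> float:
    """Mean separation (in pooled-SD units) of two unit-variance normals that
    yields the requested AUC: delta = sqrt(2) * Phi^-1(AUC)."""
    if not (0.5 < target_auc < 1.0):
        raise ParameterError(f"target AUC must lie in (0.5, 1), got {target_auc}")
    return float(np.sqrt(2.0) * stats.norm.ppf(target_auc))


def _lognormal_params(median: float, iqr: tuple[float, float]):
    """(mu, sigma) of a log-normal from its median and quartiles."""
    mu = np.log(median)
    sigma = (np.log(iqr[1]) - np.log(iqr[0])) / _IQR_Z
    return mu, sigma


#: per-compartment (median, (q1, q3)) anchors by nodal status, x1e-3 mm^2/s
GROUP_ANCHORS = {
    "adc_tumor": {0: (0.94, (0.81, 1.12)), 1: (0.75, (0.715, 0.93))},
    "adc_shell1": {0: (1.49, (1.43, 1.62)), 1: (1.62, (1.44, 1.78))},
    "adc_shell2": {0: (1.39, (1.31, 1.54)), 1: (1.48, (1.23, 1.67))},
    "adc_shell3": {0: (1.56, (1.48, 1.66)), 1: (1.72, (1.42, 1.83))},
    "adc_reference": {0: (1.55, (1.50, 1.69)), 1: (1.55, (1.50, 1.69))},
}

#: tumor volume (mm^3): median 3999, IQR 1123-9618, mildly higher in pN+
VOLUME_ANCHOR = (3999.0, (1123.0, 9618.0))


@dataclass
class CohortSimSpec:
    """Statistical structure of a simulated patient cohort."""

    n_patients: int = 68
    prevalence_pn: float = 27 / 68
    fixed_count: bool = True          # exact positive count round(n * prevalence)
    prevalence_lvi: float = 17 / 68
    subtype_proportions: tuple[float, ...] = (13 / 68, 44 / 68, 6 / 68, 5 / 68)
    grade_proportions: tuple[float, ...] = (22 / 68, 35 / 68, 11 / 68)
    ki67_anchor: tuple[float, tuple[float, float]] = (0.25, (0.15, 0.43))
    shell_factor_rho: float = 0.5     # shared parenchymal factor, log scale
    cellularity_coupling: float = 0.55  # Ki-67/grade/LVI vs tumor cellularity
    target_aucs: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.prevalence_pn < 1) or not (0 < self.prevalence_lvi < 1):
            raise ParameterError("prevalences must lie in (0, 1)")
        if abs(sum(self.subtype_proportions) - 1) > 1e-9:
            raise ParameterError("subtype proportions must sum to 1")
        if abs(sum(self.grade_proportions) - 1) > 1e-9:
            raise ParameterError("grade proportions must sum to 1")
        if not (0 <= self.shell_factor_rho < 1):
            raise ParameterError("shell_factor_rho must lie in [0, 1)")
        if not (0 <= self.cellularity_coupling < 1):
            raise ParameterError("cellularity_coupling must lie in [0, 1)")
        for name, auc in self.target_aucs.items():
            if not (0.5 < auc < 1.0):
                raise ParameterError(f"target AUC for {name} must lie in (0.5, 1)")


def generate_cohort(spec: CohortSimSpec | None = None) -> pd.DataFrame:
    """Simulate a patient-level cohort table (validated schema).

    Base ADC compartments are group-anchored log-normals; rADC and ratio
    columns are computed from them.  A metric listed in ``spec.target_aucs``
    is instead drawn from the binormal model calibrated to that AUC (low
    values predicting the positive class), overriding the derived column.
    """
    spec = spec or CohortSimSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    if spec.fixed_count:
        n_pos = int(round(n * spec.prevalence_pn))
        pn = np.zeros(n, dtype=int)
        pn[rng.choice(n, size=n_pos, replace=False)] = 1
    else:
        pn = (rng.random(n) < spec.prevalence_pn).astype(int)

    # latents: t = tumor cellularity (idiosyncratic), p = shared parenchymal
    # factor for shell/reference compartments
    t = rng.standard_normal(n)
    p = rng.standard_normal(n)
    rho = spec.shell_factor_rho

    values: dict[str, np.ndarray] = {}
    for name, anchors in GROUP_ANCHORS.items():
        if name == "adc_tumor":
            z = t
        else:
            z = np.sqrt(rho) * p + np.sqrt(1 - rho) * rng.standard_normal(n)
        mu = np.empty(n)
        sigma = np.empty(n)
        for g in (0, 1):
            m, s = _lognormal_params(*anchors[g])
            mu[pn == g], sigma[pn == g] = m, s
        values[name] = np.exp(mu + sigma * z)

    adc = {k: values[k] for k in GROUP_ANCHORS}
    table = pd.DataFrame({"id": [f"P{i + 1:03d}" for i in range(n)]})
    for k, v in adc.items():
        table[k] = v
    for i, shell in enumerate(("shell1", "shell2", "shell3"), start=1):
        table[f"ratio_shell{i}"] = adc["adc_tumor"] / adc[f"adc_{shell}"]
    table["radc_tumor"] = adc["adc_tumor"] / adc["adc_reference"]
    for i in (1, 2, 3):
        table[f"radc_shell{i}"] = adc[f"adc_shell{i}"] / adc["adc_reference"]

    # target-AUC overrides: binormal marker on the log scale (low -> positive)
    for name, auc in spec.target_aucs.items():
        delta = binormal_shift(auc)
        z = rng.standard_normal(n)
        z[pn == 1] -= delta
        base_median = float(np.median(table[name])) if name in table else 1.0
        table[name] = np.exp(np.log(base_median) + 0.25 * z)

    mu_v, s_v = _lognormal_params(*VOLUME_ANCHOR)
    zv = rng.standard_normal(n) + 0.3 * pn   # larger tumors mildly enrich pN+
    table["tumor_volume_mm3"] = np.exp(mu_v + s_v * zv)

    # Ki-67 / grade / LVI couple to tumor cellularity (low ADC <-> high Ki-67)
    gam = spec.cellularity_coupling
    k_lat = -gam * t + np.sqrt(1 - gam**2) * rng.standard_normal(n)
    mu_k, s_k = _lognormal_params(*spec.ki67_anchor)
    table["ki67"] = np.clip(np.exp(mu_k + s_k * k_lat), 0.0, 1.0)

    g_lat = -gam * t + np.sqrt(1 - gam**2) * rng.standard_normal(n)
    g1, g2, _ = spec.grade_proportions
    cut1, cut2 = np.quantile(g_lat, [g1, g1 + g2])
    table["grade"] = np.where(g_lat <= cut1, 1, np.where(g_lat <= cut2, 2, 3))

    # LVI via a logistic link on cellularity, intercept solved for prevalence
    slope = 0.8
    from scipy.optimize import brentq
    a = brentq(
        lambda c: np.mean(1 / (1 + np.exp(-(c - slope * t)))) - spec.prevalence_lvi,
        -10, 10,
    )
    table["LVI"] = (rng.random(n) < 1 / (1 + np.exp(-(a - slope * t)))).astype(int)

    table["molecular_subtype"] = rng.choice(
        SUBTYPES, size=n, p=spec.subtype_proportions
    )
    table["pN_status"] = pn
    return validate_cohort(table)


def simulate_marker(n_pos: int, n_neg: int, target_auc: float,
                    rng: np.random.Generator):
    """Binormal marker (high predicts positive) at a calibrated AUC; returns
    (scores, labels)."""
    delta = binormal_shift(target_auc)
    scores = np.concatenate([
        rng.standard_normal(n_neg),
        rng.standard_normal(n_pos) + delta,
    ])
    labels = np.concatenate([np.zeros(n_neg, int), np.ones(n_pos, int)])
    return scores, labels
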