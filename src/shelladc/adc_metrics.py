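"""Per-patient quantitative ADC metrics.

Twelve quantities per case: mean ADC of the (eroded) tumor VOI, of each of the
three peritumoral shells, and of the contralateral reference VOI; the four
normalized values rADC = ADC / reference-ADC; and the three per-patient
intratumoral-to-peritumoral ratios ADC_tumor / ADC_shell_k.  Tumor volume is
reported for the un-eroded mask (voxel count x voxel volume).

Empty compartments yield NaN ("missing"), never 0, so cohort statistics drop
those patients pairwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .errors import GeometryError
from .shell_geometry import ShellSet
from .volume_io import BinaryMask, ImageVolume


@dataclass
class PatientMetrics:
    adc_tumor: float
    adc_shell1: float
    adc_shell2: float
    adc_shell3: float
    adc_reference: float
    radc_tumor: float
    radc_shell1: float
    radc_shell2: float
    radc_shell3: float
    ratio_shell1: float
    ratio_shell2: float
    ratio_shell3: float
    tumor_volume_mm3: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def mean_in_mask(volume: ImageVolume, mask: BinaryMask) -> float:
    """Voxel-wise mean of the volume over the mask; NaN voxels are excluded
    from numerator and count; an empty mask yields NaN with a warning."""
    if volume.data.shape != mask.data.shape:
        raise GeometryError(
            f"volume shape {volume.data.shape} != mask shape {mask.data.shape}"
        )
    if mask.is_empty:
        warnings.warn(f"empty {mask.role} mask: metric recorded as missing",
                      stacklevel=2)
        return float("nan")
    values = np.asarray(volume.data, dtype=float)[mask.data]
    if np.isnan(values).all():
        warnings.warn("all voxels missing in mask: metric recorded as missing",
                      stacklevel=2)
        return float("nan")
    return float(np.nanmean(values))


def normalize_radc(value: float, reference: float) -> float:
    """value / reference; missing or non-positive reference propagates NaN."""
    if not np.isfinite(reference) or reference <= 0:
        warnings.warn("missing or non-positive reference ADC: rADC is missing",
                      stacklevel=2)
        return float("nan")
    if not np.isfinite(value):
        return float("nan")
    return float(value) / float(reference)


def tumor_to_shell_ratio(adc_tumor: float, adc_shell: float) -> float:
    """Per-patient intratumoral / peritumoral ADC ratio."""
    if not np.isfinite(adc_shell) or adc_shell <= 0 or not np.isfinite(adc_tumor):
        return float("nan")
    return float(adc_tumor) / float(adc_shell)


def extract_patient_metrics(
    volume: ImageVolume,
    shells: ShellSet,
    reference_voi: BinaryMask | None = None,
) -> PatientMetrics:
    """Assemble all per-patient metrics from a volume and its ShellSet.

    ``reference_voi`` overrides ``shells.reference_voi`` when given (manual
    contralateral placement).
    """
    if volume.data.shape != shells.tumor_mask.data.shape:
        raise GeometryError("shells were not built on this volume's grid")
    if len(shells.shells) != 3:
        raise GeometryError(
            f"expected 3 peritumoral shells, got {len(shells.shells)}"
        )
    ref_mask = reference_voi if reference_voi is not None else shells.reference_voi

    adc_tumor = mean_in_mask(volume, shells.tumor_voi)
    shell_means = [mean_in_mask(volume, s) for s in shells.shells]
    adc_reference = (
        mean_in_mask(volume, ref_mask) if ref_mask is not None else float("nan")
    )

    radcs = [normalize_radc(v, adc_reference)
             for v in (adc_tumor, *shell_means)]
    ratios = [tumor_to_shell_ratio(adc_tumor, s) for s in shell_means]

    volume_mm3 = shells.tumor_mask.n_voxels * (
        float(np.prod(shells.tumor_mask.spacing))
    )
    return PatientMetrics(
        adc_tumor=adc_tumor,
        adc_shell1=shell_means[0],
        adc_shell2=shell_means[1],
        adc_shell3=shell_means[2],
        adc_reference=adc_reference,
        radc_tumor=radcs[0],
        radc_shell1=radcs[1],
        radc_shell2=radcs[2],
        radc_shell3=radcs[3],
        ratio_shell1=ratios[0],
        ratio_shell2=ratios[1],
        ratio_shell3=ratios[2],
        tumor_volume_mm3=volume_mm3,
    )
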