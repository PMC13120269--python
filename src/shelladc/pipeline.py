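"""End-to-end per-case processing: resample, build shells, measure."""

from __future__ import annotations

from .adc_metrics import PatientMetrics, extract_patient_metrics
from .shell_geometry import (
    ShellSet,
    ShellSpec,
    build_shells,
    mirror_reference_voi,
    resample_isotropic,
)
from .volume_io import BinaryMask, ImageVolume


def process_case(
    volume: ImageVolume,
    tumor: BinaryMask,
    exclusion: BinaryMask | None = None,
    reference: BinaryMask | None = None,
    shell_specs: list[ShellSpec] | None = None,
    target_mm: float = 1.0,
) -> tuple[PatientMetrics, ShellSet]:
    """Run the full measurement pipeline for one case.

    Resamples everything to ``target_mm`` isotropic voxels, erodes the tumor,
    builds the concentric shells (removing excluded voxels), mirrors the
    tumor VOI into the contralateral breast unless a manual reference mask is
    supplied, and extracts the per-patient metrics.
    """
    masks = [tumor] + ([exclusion] if exclusion is not None else []) \
        + ([reference] if reference is not None else [])
    iso_volume, iso_masks = resample_isotropic(volume, masks, target_mm)
    iso_tumor = iso_masks[0]
    iso_excl = iso_masks[1] if exclusion is not None else None
    iso_ref = iso_masks[-1] if reference is not None else None

    shells = build_shells(iso_tumor, shell_specs, iso_excl)
    if iso_ref is None:
        iso_ref = mirror_reference_voi(shells.tumor_voi, iso_volume)
    shells.reference_voi = iso_ref
    metrics = extract_patient_metrics(iso_volume, shells)
    return metrics, shells
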