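"""Concentric peritumoral shell construction on resampled ADC volumes.

The measurement geometry is: (1) resample everything to 1 mm isotropic voxels,
(2) erode the tumor mask by one voxel (6-connected) to obtain the intratumoral
measurement VOI, (3) compute the Euclidean distance field from the *original*
tumor surface, (4) slice the outside into half-open distance bands
(0,2] / (2,5] / (5,10] mm, removing excluded voxels, and (5) mirror the tumor
VOI across the midsagittal plane to obtain a contralateral reference VOI of
identical size at the same craniocaudal level.

Shell distances are measured from the un-eroded tumor boundary: the erosion
exists only to keep intratumoral signal out of the tumor mean, not to shift
the anatomical shells inward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError, GeometryError, ParameterError
from .volume_io import BinaryMask, ImageVolume

DEFAULT_SHELLS_MM = ((0.0, 2.0), (2.0, 5.0), (5.0, 10.0))


@dataclass(frozen=True)
class ShellSpec:
    """A half-open distance band (inner_mm, outer_mm] from the tumor surface."""

    inner_mm: float
    outer_mm: float

    def __post_init__(self) -> None:
        if not (0 <= self.inner_mm < self.outer_mm):
            raise ParameterError(
                f"need 0 <= inner < outer, got ({self.inner_mm}, {self.outer_mm}]"
            )


def default_shell_specs() -> list[ShellSpec]:
    return [ShellSpec(a, b) for a, b in DEFAULT_SHELLS_MM]


@dataclass
class ShellSet:
    """All measurement VOIs for one case, with QC flags."""

    tumor_voi: BinaryMask            # eroded tumor (measurement VOI)
    tumor_mask: BinaryMask           # original (un-eroded) tumor, for volume
    shells: list[BinaryMask]
    specs: list[ShellSpec]
    distance_field: ImageVolume      # mm outside the tumor surface, 0 inside
    reference_voi: BinaryMask | None = None
    clipped: list[bool] = field(default_factory=list)
    empty: list[bool] = field(default_factory=list)
    erosion_fallback: bool = False   # erosion emptied the VOI; original retained


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _resample_grid(shape, spacing, target_mm):
    """New shape covering the same voxel-center extent at isotropic spacing."""
    return tuple(
        int(np.floor((n - 1) * s / target_mm + 0.5)) + 1
        for n, s in zip(shape, spacing)
    )


def _coordinates(new_shape, spacing, target_mm):
    axes = [
        np.arange(n_new) * target_mm / s
        for n_new, s in zip(new_shape, spacing)
    ]
    return np.meshgrid(*axes, indexing="ij")


def resample_isotropic(
    volume: ImageVolume,
    masks: list[BinaryMask] | None = None,
    target_mm: float = 1.0,
) -> tuple[ImageVolume, list[BinaryMask]]:
    """Resample a volume (tri-linear) and its masks (nearest neighbor) to an
    isotropic grid of ``target_mm`` voxels, preserving origin and extent."""
    if target_mm <= 0:
        raise ParameterError(f"target_mm must be positive, got {target_mm}")
    masks = masks or []
    for m in masks:
        if not volume.same_grid(m):
            raise GeometryError("mask grid does not match volume before resampling")
    new_shape = _resample_grid(volume.shape, volume.spacing, target_mm)
    coords = np.array(_coordinates(new_shape, volume.spacing, target_mm))
    new_data = ndimage.map_coordinates(
        np.asarray(volume.data, dtype=float), coords, order=1, mode="nearest"
    )
    out_volume = ImageVolume(new_data, (target_mm,) * 3, volume.origin)
    out_masks = []
    for m in masks:
        md = ndimage.map_coordinates(
            m.data.astype(np.uint8), coords, order=0, mode="nearest"
        )
        out_masks.append(BinaryMask(md, (target_mm,) * 3, m.origin, m.role))
    return out_volume, out_masks


# ---------------------------------------------------------------------------
# Morphology and distance
# ---------------------------------------------------------------------------

_CROSS_3D = ndimage.generate_binary_structure(3, 1)  # 6-connected


def erode_one_voxel(mask: BinaryMask) -> BinaryMask:
    """One-voxel binary erosion with the 6-connected (face) structuring element.

    If erosion empties the mask (degenerate, thin tumors) the original mask is
    returned unchanged with a warning, so downstream measurement still works.
    """
    if mask.is_empty:
        raise EmptyMaskError("cannot erode an empty mask")
    eroded = ndimage.binary_erosion(mask.data, structure=_CROSS_3D)
    if not eroded.any():
        warnings.warn(
            "one-voxel erosion emptied the tumor VOI; falling back to the "
            "un-eroded mask",
            stacklevel=2,
        )
        return mask.with_data(mask.data.copy())
    return mask.with_data(eroded)


def boundary_distance_field(tumor: BinaryMask) -> ImageVolume:
    """Euclidean distance (mm) from each outside voxel to the nearest tumor
    voxel center; 0 inside the tumor.  Uses the physical voxel spacing."""
    if tumor.is_empty:
        raise EmptyMaskError("cannot compute a distance field from an empty tumor")
    dist = ndimage.distance_transform_edt(~tumor.data, sampling=tumor.spacing)
    return ImageVolume(dist, tumor.spacing, tumor.origin)


# ---------------------------------------------------------------------------
# Shell construction
# ---------------------------------------------------------------------------

def _check_specs(specs: list[ShellSpec]) -> None:
    for a, b in zip(specs, specs[1:]):
        if b.inner_mm < a.outer_mm:
            raise ParameterError(
                f"shell specs must be sorted and non-overlapping: "
                f"({a.inner_mm},{a.outer_mm}] then ({b.inner_mm},{b.outer_mm}]"
            )


def build_shells(
    tumor: BinaryMask,
    specs: list[ShellSpec] | None = None,
    exclusion: BinaryMask | None = None,
) -> ShellSet:
    """Build the eroded tumor VOI and the concentric peritumoral shells.

    Shell ``k`` holds the voxels with ``inner < d <= outer`` (``d`` = Euclidean
    distance to the un-eroded tumor surface) that lie inside the image and
    outside both the tumor and the exclusion mask.  A shell is flagged
    ``clipped`` when tissue at its distances would fall outside the grid, and
    ``empty`` when no voxel survives.
    """
    if tumor.is_empty:
        raise EmptyMaskError("tumor mask is empty")
    specs = list(specs) if specs is not None else default_shell_specs()
    _check_specs(specs)
    if exclusion is not None and tumor.shape != exclusion.shape:
        raise GeometryError("exclusion mask grid does not match tumor grid")

    dist = boundary_distance_field(tumor)
    d = dist.data
    eroded = erode_one_voxel(tumor)
    fallback = eroded.n_voxels == tumor.n_voxels
    eroded = eroded.with_data(eroded.data, role="tumor")

    excl = exclusion.data if exclusion is not None else np.zeros(tumor.shape, bool)
    outside = ~tumor.data & ~excl

    # minimum outside-distance reachable on each grid face; if a face sits
    # closer than a shell's outer radius, part of that band lies off-grid
    face_min = min(
        d[0].min(), d[-1].min(),
        d[:, 0].min(), d[:, -1].min(),
        d[:, :, 0].min(), d[:, :, -1].min(),
    )

    shells, clipped, empty = [], [], []
    for s in specs:
        band = outside & (d > s.inner_mm) & (d <= s.outer_mm)
        shells.append(BinaryMask(band, tumor.spacing, tumor.origin, "shell"))
        clipped.append(bool(face_min < s.outer_mm))
        empty.append(not band.any())

    return ShellSet(
        tumor_voi=eroded,
        tumor_mask=tumor,
        shells=shells,
        specs=specs,
        distance_field=dist,
        clipped=clipped,
        empty=empty,
        erosion_fallback=fallback,
    )


def mirror_reference_voi(tumor_voi: BinaryMask, volume: ImageVolume) -> BinaryMask:
    """Reflect the tumor VOI across the mid-plane of the left-right axis.

    This realizes a contralateral reference VOI of identical voxel count at
    the same craniocaudal level.  If the reflection would overlap the tumor
    itself (midline lesions), a geometry error instructs the caller to supply
    a manual reference mask instead.
    """
    if tumor_voi.is_empty:
        raise EmptyMaskError("tumor VOI is empty")
    if not volume.same_grid(tumor_voi):
        raise GeometryError("tumor VOI grid does not match volume")
    mirrored = tumor_voi.data[::-1, :, :].copy()
    if (mirrored & tumor_voi.data).any():
        raise GeometryError(
            "mirrored reference VOI overlaps the tumor (midline lesion); "
            "supply a manual reference mask"
        )
    return BinaryMask(mirrored, tumor_voi.spacing, tumor_voi.origin, "reference")
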