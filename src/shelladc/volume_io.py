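"""Reading, writing, and validating ADC volumes, masks, and cohort tables.

Volumes are held in a canonical axis order (x = left-right, y =
anterior-posterior, z = superior-inferior); NIfTI images are reoriented to the
closest RAS orientation on load so the contralateral mirror plane is well
defined.  Voxel indices are 0-based and physical coordinates are voxel-center
based: the center of voxel ``(i, j, k)`` sits at ``origin + (i, j, k) * spacing``.

ADC values are stored in units of 1e-3 mm^2/s throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    DimensionalityError,
    EmptyMaskError,
    GeometryError,
    ValidationError,
)

#: tolerance (mm) when checking that a mask's grid matches its reference volume
GRID_TOL_MM = 1e-3

MASK_ROLES = ("tumor", "shell", "exclusion", "reference")

#: the twelve per-patient metrics plus tumor volume, in reporting order
METRIC_COLUMNS = [
    "adc_tumor",
    "adc_shell1",
    "adc_shell2",
    "adc_shell3",
    "adc_reference",
    "radc_tumor",
    "radc_shell1",
    "radc_shell2",
    "radc_shell3",
    "ratio_shell1",
    "ratio_shell2",
    "ratio_shell3",
    "tumor_volume_mm3",
]

SUBTYPES = ("LumA", "LumB", "HER2E", "TNBC")
LABEL_COLUMNS = ["pN_status", "LVI", "molecular_subtype", "grade", "ki67"]


@dataclass
class ImageVolume:
    """A 3D scalar grid with physical spacing and origin (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"volume must be 3D, got {self.data.ndim} dimensions"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        if min(self.data.shape) < 1:
            raise DimensionalityError(f"degenerate shape {self.data.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "ImageVolume | BinaryMask", tol: float = GRID_TOL_MM) -> bool:
        return (
            self.data.shape == other.data.shape
            and all(abs(a - b) <= tol for a, b in zip(self.spacing, other.spacing))
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )


@dataclass
class BinaryMask:
    """Voxel membership on the grid of a paired :class:`ImageVolume`.

    ``role`` distinguishes tumor / shell / exclusion / reference masks; only
    exclusion masks may be empty.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    role: str = "tumor"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) != 0
        if self.data.ndim != 3:
            raise DimensionalityError(f"mask must be 3D, got {self.data.ndim} dimensions")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.role not in MASK_ROLES:
            raise ValidationError(f"unknown mask role {self.role!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def is_empty(self) -> bool:
        return not self.data.any()

    def with_data(self, data: np.ndarray, role: str | None = None) -> "BinaryMask":
        return BinaryMask(data, self.spacing, self.origin, role or self.role)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _load_canonical(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(f"{path}: expected a 3D image, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return data, spacing, origin


def read_volume(path: str | Path) -> ImageVolume:
    """Read a NIfTI-1 ADC map, reoriented to the canonical axis order."""
    data, spacing, origin = _load_canonical(path)
    return ImageVolume(np.asarray(data, dtype=float), spacing, origin)


def read_mask(path: str | Path, reference: ImageVolume, role: str = "tumor") -> BinaryMask:
    """Read a NIfTI mask, binarize it, and check it shares ``reference``'s grid.

    Exclusion masks may be empty; every other role must contain voxels.
    """
    data, spacing, origin = _load_canonical(path)
    mask = BinaryMask(data, spacing, origin, role)
    if not reference.same_grid(mask):
        raise GeometryError(
            f"mask grid {mask.shape}/{spacing}/{origin} does not match reference "
            f"{reference.shape}/{reference.spacing}/{reference.origin} "
            f"within {GRID_TOL_MM} mm"
        )
    if mask.is_empty and role != "exclusion":
        raise EmptyMaskError(f"{path}: {role} mask contains no voxels")
    return mask


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64),
                          _affine(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.spacing, mask.origin))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate the per-patient schema; returns the (typed) table.

    Unknown columns are preserved untouched.  Missing cells stay NaN and are
    handled pairwise by the statistics layer.
    """
    if "id" not in table.columns:
        raise ValidationError("cohort table must have an 'id' column")
    if table["id"].duplicated().any():
        dupes = table.loc[table["id"].duplicated(), "id"].tolist()
        raise ValidationError(f"duplicate patient ids: {dupes}")
    for col in METRIC_COLUMNS:
        if col in table.columns:
            vals = pd.to_numeric(table[col], errors="coerce")
            if (vals.dropna() <= 0).any():
                raise ValidationError(f"column {col} must be positive where present")
            table[col] = vals
    for col in ("pN_status", "LVI"):
        if col in table.columns:
            vals = pd.to_numeric(table[col], errors="coerce")
            bad = vals.dropna()[~vals.dropna().isin([0, 1])]
            if len(bad):
                raise ValidationError(f"column {col} must be 0/1, got {bad.unique()}")
            table[col] = vals
    if "molecular_subtype" in table.columns:
        sub = table["molecular_subtype"].dropna()
        bad = sub[~sub.isin(SUBTYPES)]
        if len(bad):
            raise ValidationError(
                f"molecular_subtype outside {SUBTYPES}: {sorted(bad.unique())}"
            )
    if "grade" in table.columns:
        vals = pd.to_numeric(table["grade"], errors="coerce")
        bad = vals.dropna()[~vals.dropna().isin([1, 2, 3])]
        if len(bad):
            raise ValidationError(f"grade must be 1/2/3, got {bad.unique()}")
        table["grade"] = vals
    if "ki67" in table.columns:
        vals = pd.to_numeric(table["ki67"], errors="coerce")
        out = vals.dropna()[(vals.dropna() < 0) | (vals.dropna() > 1)]
        if len(out):
            raise ValidationError("ki67 must lie in [0, 1]")
        table["ki67"] = vals
    return table


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a patient-level cohort CSV (one row per patient)."""
    return validate_cohort(pd.read_csv(path))


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def prevalence(table: pd.DataFrame, outcome: str = "pN_status") -> float:
    """Fraction of outcome-positive patients among those with a known label."""
    labels = pd.to_numeric(table[outcome], errors="coerce").dropna()
    if labels.empty:
        raise ValidationError(f"no non-missing values in column {outcome}")
    return float((labels == 1).mean())
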