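"""Volume and mask I/O with a single-spatial-reference contract.

All volumes entering one analysis must live on the same grid (shape and
affine).  Nothing here resamples or reorients: inputs are assumed to be
already spatially normalized (e.g. to an MNI template), and any grid
mismatch is reported as an error rather than silently interpolated away.

Voxel indices are 0-based throughout; user-facing coordinates are world
millimetres obtained through the NIfTI affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "MetabolicVolume",
    "BinaryMask",
    "AlignmentReport",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "check_cohort_alignment",
    "voxel_to_mm",
    "mm_to_voxel",
]

#: elementwise tolerance when comparing affines across a cohort
AFFINE_ATOL = 1e-4


@dataclass
class MetabolicVolume:
    """One subject's 3D metabolic map (e.g. a time-averaged FDG-PET image).

    Attributes
    ----------
    data : ndarray, shape (i, j, k)
        Voxel intensities in image units (regional glucose metabolism).
    affine : ndarray, shape (4, 4)
        Voxel-index to world-millimetre transform; must be invertible.
    subject_id : str
        Identifier matching the participants table.
    """

    data: np.ndarray
    affine: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"volume data must be 3D, got shape {self.data.shape}"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        _require_invertible(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BinaryMask:
    """A boolean region mask sharing the cohort's spatial reference."""

    data: np.ndarray
    affine: np.ndarray
    label: str = "mask"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) != 0
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not self.data.any():
            raise ValueError(f"mask {self.label!r} has no true voxel")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def indices(self) -> np.ndarray:
        """(n, 3) array of true-voxel indices in C order."""
        return np.argwhere(self.data)


@dataclass
class AlignmentReport:
    """Outcome of a cohort-wide grid consistency check."""

    passed: bool
    reference_shape: tuple[int, ...]
    offenders: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


def _require_invertible(affine: np.ndarray) -> None:
    if not np.all(np.isfinite(affine)) or abs(np.linalg.det(affine)) < 1e-12:
        raise ValueError("affine is not invertible")


def load_volume(path: str | Path, subject_id: str | None = None) -> MetabolicVolume:
    """Load a 3D NIfTI volume.

    A trailing singleton 4th dimension is squeezed.  True 4D images are
    rejected: this pipeline consumes one time-averaged map per subject.
    NIfTI scl_slope/scl_inter scaling is applied (via nibabel); intensities
    are otherwise untouched.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    shape = img.shape
    if len(shape) > 4:
        raise ValueError(f"{path.name}: expected a 3D image, got shape {shape}")
    if len(shape) == 4 and shape[3] != 1:
        raise ValueError(
            f"{path.name}: image has {shape[3]} frames; "
            "time-average your input first (one 3D map per subject)"
        )
    data = np.asarray(img.get_fdata(dtype=np.float64))
    if data.ndim == 4:
        data = data[..., 0]
    sid = subject_id if subject_id is not None else _stem(path)
    return MetabolicVolume(data=data, affine=np.asarray(img.affine), subject_id=sid)


def _stem(path: Path) -> str:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return path.stem


def save_volume(volume: MetabolicVolume, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), volume.affine), str(path))
    return path


def load_mask(path: str | Path, label: str = "mask") -> BinaryMask:
    """Load a mask image; any nonzero voxel counts as true."""
    vol = load_volume(path)
    return BinaryMask(data=vol.data != 0, affine=vol.affine, label=label)


def save_mask(mask: BinaryMask, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), mask.affine), str(path))
    return path


def check_cohort_alignment(
    volumes: list[MetabolicVolume],
    masks: list[BinaryMask] | None = None,
) -> AlignmentReport:
    """Verify that every volume and mask shares one grid.

    Shapes must be equal exactly; affines must agree elementwise within
    ``AFFINE_ATOL``.  The first volume defines the reference.  The report
    names every offending subject_id / mask label instead of stopping at
    the first.
    """
    if not volumes:
        raise ValueError("need at least one volume")
    ref_shape = volumes[0].shape
    ref_affine = volumes[0].affine
    offenders: list[str] = []

    def _check(name: str, shape: tuple[int, ...], affine: np.ndarray) -> None:
        if tuple(shape) != tuple(ref_shape):
            offenders.append(f"{name}: shape {tuple(shape)} != {tuple(ref_shape)}")
        elif not np.allclose(affine, ref_affine, rtol=0.0, atol=AFFINE_ATOL):
            offenders.append(f"{name}: affine differs by more than {AFFINE_ATOL}")

    for vol in volumes[1:]:
        _check(vol.subject_id or "<volume>", vol.shape, vol.affine)
    for mask in masks or []:
        _check(f"mask {mask.label!r}", mask.data.shape, mask.affine)

    return AlignmentReport(passed=not offenders, reference_shape=tuple(ref_shape),
                           offenders=offenders)


def voxel_to_mm(index: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Map 0-based voxel indices to world mm coordinates."""
    return nib.affines.apply_affine(np.asarray(affine, dtype=float),
                                    np.asarray(index, dtype=float))


def mm_to_voxel(
    coord: np.ndarray,
    affine: np.ndarray,
    shape: tuple[int, int, int] | None = None,
) -> np.ndarray:
    """Map world mm coordinates to the nearest 0-based voxel index.

    If ``shape`` is given, an out-of-grid result raises ``ValueError``.
    """
    affine = np.asarray(affine, dtype=float)
    _require_invertible(affine)
    idx_f = nib.affines.apply_affine(np.linalg.inv(affine),
                                     np.asarray(coord, dtype=float))
    idx = np.rint(idx_f).astype(int)
    if shape is not None:
        lo_ok = np.all(idx >= 0, axis=-1)
        hi_ok = np.all(idx < np.asarray(shape), axis=-1)
        if not np.all(lo_ok & hi_ok):
            raise ValueError(f"mm coordinate {np.asarray(coord)} maps outside grid {shape}")
    return idx
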