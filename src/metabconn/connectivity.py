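"""Seed-based metabolic covariance connectivity.

For a single time-averaged metabolic map, the connectivity between a seed
region *i* and a spherical searchlight *j* centred on a voxel is the
distributional similarity

    S = exp( -(m_i - m_j)^2 / (2 (sigma_i^2 + sigma_j^2)) )

where ``m`` and ``sigma`` are the mean and (sample) standard deviation of
the voxel intensities inside each region.  S lies in (0, 1]: it is 1 when
the regional means coincide and decays as they separate, on a scale set by
the combined within-region spatial variability.  The statistics are spatial
(over voxels of the single averaged map), not temporal.

Sweeping the searchlight centre over every brain voxel turns one subject's
volume into a similarity map, the per-subject input to group inference.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .io import BinaryMask, MetabolicVolume, check_cohort_alignment

__all__ = [
    "RegionStats",
    "SearchlightSpec",
    "SimilarityMap",
    "DegenerateVarianceWarning",
    "region_stats",
    "similarity",
    "sphere_voxels",
    "sphere_offsets",
    "searchlight_map",
    "default_brain_mask",
    "save_similarity_map",
]


class DegenerateVarianceWarning(UserWarning):
    """Both regions have zero spatial variance; S is set by its limit."""


@dataclass(frozen=True)
class RegionStats:
    """Mean/SD summary of metabolic intensity over a voxel set.

    ``sigma`` is the sample standard deviation (n-1 denominator) and is
    only defined for regions of at least two voxels.
    """

    m: float
    sigma: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("region must contain at least one voxel")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


@dataclass(frozen=True)
class SearchlightSpec:
    """Sphere searchlight parameters.

    radius_mm : float
        Sphere radius in millimetres (default 6 mm, i.e. two voxels on a
        3 mm grid).  The choice matters and is recorded in output metadata.
    min_voxels : int
        Minimum in-mask sphere size for a defined similarity value;
        at least 2 so the sphere SD exists.
    """

    radius_mm: float = 6.0
    min_voxels: int = 2

    def __post_init__(self) -> None:
        if not (self.radius_mm > 0):
            raise ValueError("radius_mm must be positive")
        if self.min_voxels < 2:
            raise ValueError("min_voxels must be >= 2")


@dataclass
class SimilarityMap:
    """Per-subject 3D map of seed-to-searchlight similarity values.

    Undefined voxels (outside the brain mask, or with spheres below
    ``spec.min_voxels``) are NaN.  The seed mask is carried along so that
    downstream reports can flag seed-overlapping voxels; they are computed
    like any other voxel, not excluded.
    """

    data: np.ndarray
    affine: np.ndarray
    subject_id: str
    seed_stats: RegionStats
    spec: SearchlightSpec
    seed_mask: BinaryMask | None = None

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.data)


def region_stats(volume: MetabolicVolume, mask: BinaryMask) -> RegionStats:
    """Mean and sample SD of a volume's intensities over a mask.

    Requires at least two masked voxels (so sigma exists) and finite
    intensities throughout the region.
    """
    if mask.data.shape != volume.shape:
        raise ValueError("mask grid does not match volume grid")
    values = volume.data[mask.data]
    if values.size < 2:
        raise ValueError(
            f"region {mask.label!r} has {values.size} voxel(s); need >= 2"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError(f"non-finite intensity inside region {mask.label!r}")
    return RegionStats(
        m=float(values.mean()),
        sigma=float(values.std(ddof=1)),
        n_voxels=int(values.size),
    )


def similarity(stats_i: RegionStats, stats_j: RegionStats) -> float:
    """Gaussian similarity between two regional intensity distributions.

    Degenerate case (both variances zero): S is defined by the limit —
    1 when the means coincide, 0 otherwise — and a
    :class:`DegenerateVarianceWarning` is emitted.
    """
    denom = stats_i.sigma**2 + stats_j.sigma**2
    diff = stats_i.m - stats_j.m
    if denom == 0.0:
        warnings.warn(
            "both regions have zero spatial variance; similarity set to "
            f"{'1 (equal means)' if diff == 0.0 else '0 (unequal means)'}",
            DegenerateVarianceWarning,
            stacklevel=2,
        )
        return 1.0 if diff == 0.0 else 0.0
    return float(np.exp(-(diff**2) / (2.0 * denom)))


def sphere_offsets(spec: SearchlightSpec, affine: np.ndarray) -> np.ndarray:
    """Integer index offsets whose voxel-centre distance is <= radius_mm.

    Distances are Euclidean in world space, using the affine's linear part,
    so anisotropic voxels are handled correctly.  Always includes (0,0,0).
    """
    lin = np.asarray(affine, dtype=float)[:3, :3]
    # smallest voxel step along each world axis bounds the search box
    step = np.sqrt((lin**2).sum(axis=0))
    reach = np.ceil(spec.radius_mm / step).astype(int)
    rng = [np.arange(-r, r + 1) for r in reach]
    grid = np.stack(np.meshgrid(*rng, indexing="ij"), axis=-1).reshape(-1, 3)
    dist = np.linalg.norm(grid @ lin.T, axis=1)
    return grid[dist <= spec.radius_mm + 1e-9]


def sphere_voxels(
    center_index: tuple[int, int, int],
    spec: SearchlightSpec,
    affine: np.ndarray,
    brain_mask: BinaryMask,
) -> np.ndarray:
    """In-mask voxel indices within radius_mm of a centre voxel.

    Returns an (n, 3) integer array; the centre voxel is included whenever
    it is inside the brain mask.
    """
    center = np.asarray(center_index, dtype=int)
    if not brain_mask.data[tuple(center)]:
        raise ValueError(f"searchlight centre {tuple(center)} outside brain mask")
    cand = center + sphere_offsets(spec, affine)
    shape = np.asarray(brain_mask.data.shape)
    ok = np.all(cand >= 0, axis=1) & np.all(cand < shape, axis=1)
    cand = cand[ok]
    inmask = brain_mask.data[tuple(cand.T)]
    return cand[inmask]


def default_brain_mask(
    volumes: list[MetabolicVolume], positive_fraction: float = 0.9
) -> BinaryMask:
    """Analysis mask: voxels positive in at least 90% of subjects' volumes.

    A deterministic, recorded fallback for when no explicit brain mask is
    supplied.
    """
    stack = np.stack([v.data > 0 for v in volumes])
    frac = stack.mean(axis=0)
    return BinaryMask(
        data=frac >= positive_fraction, affine=volumes[0].affine, label="brain"
    )


def _sphere_member_table(
    shape: tuple[int, int, int],
    brain_mask: np.ndarray,
    spec: SearchlightSpec,
    affine: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precompute, for every brain voxel, the flat indices of its sphere.

    Returns (centers_flat, members, valid) where ``members`` is
    (n_centers, n_offsets) flat indices into the volume and ``valid`` marks
    in-grid, in-mask members.  Shared across subjects on one grid.
    """
    offsets = sphere_offsets(spec, affine)
    centers = np.argwhere(brain_mask)
    cand = centers[:, None, :] + offsets[None, :, :]  # (n_centers, n_off, 3)
    shape_arr = np.asarray(shape)
    ingrid = np.all(cand >= 0, axis=2) & np.all(cand < shape_arr, axis=2)
    clipped = np.clip(cand, 0, shape_arr - 1)
    flat = np.ravel_multi_index(
        (clipped[..., 0], clipped[..., 1], clipped[..., 2]), shape
    )
    valid = ingrid & brain_mask.ravel()[flat]
    centers_flat = np.ravel_multi_index(tuple(centers.T), shape)
    return centers_flat, flat, valid


def searchlight_map(
    volume: MetabolicVolume,
    seed: BinaryMask,
    brain_mask: BinaryMask,
    spec: SearchlightSpec = SearchlightSpec(),
    global_mean_scale: bool = False,
    _table: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> SimilarityMap:
    """Similarity of the seed to a sphere centred on every brain voxel.

    Voxels whose in-mask sphere has fewer than ``spec.min_voxels`` members
    are left undefined (NaN).  Seed-overlapping centres are computed like
    any other; the seed mask rides along in the result for flagging.

    ``global_mean_scale`` divides the volume by its in-brain mean first
    (proportional scaling), making the map invariant to multiplicative
    intensity rescaling; off by default since the similarity already
    ignores additive offsets.

    ``_table`` lets callers reuse the precomputed sphere-membership table
    across subjects on an identical grid (see :func:`_sphere_member_table`).
    """
    report = check_cohort_alignment([volume], [seed, brain_mask])
    if not report:
        raise ValueError("grid mismatch: " + "; ".join(report.offenders))

    if global_mean_scale:
        gmean = volume.data[brain_mask.data].mean()
        if gmean <= 0:
            raise ValueError("non-positive global mean; cannot scale")
        volume = MetabolicVolume(
            data=volume.data / gmean,
            affine=volume.affine,
            subject_id=volume.subject_id,
        )

    seed_st = region_stats(volume, seed)
    if _table is None:
        _table = _sphere_member_table(
            volume.shape, brain_mask.data, spec, volume.affine
        )
    centers_flat, members, valid = _table

    flat = volume.data.ravel()
    vals = flat[members]
    vals = np.where(valid, vals, np.nan)
    counts = valid.sum(axis=1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        m_j = np.nanmean(vals, axis=1)
        sd_j = np.nanstd(vals, axis=1, ddof=1)

    denom = seed_st.sigma**2 + sd_j**2
    diff = seed_st.m - m_j
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.exp(-(diff**2) / (2.0 * denom))
    degenerate = denom == 0.0
    if np.any(degenerate & (counts >= spec.min_voxels)):
        warnings.warn(
            "degenerate zero-variance searchlight sphere(s) encountered",
            DegenerateVarianceWarning,
            stacklevel=2,
        )
        s = np.where(degenerate, np.where(diff == 0.0, 1.0, 0.0), s)
    s = np.where(counts >= spec.min_voxels, s, np.nan)

    out = np.full(volume.data.size, np.nan)
    out[centers_flat] = s
    return SimilarityMap(
        data=out.reshape(volume.shape),
        affine=volume.affine,
        subject_id=volume.subject_id,
        seed_stats=seed_st,
        spec=spec,
        seed_mask=seed,
    )


def save_similarity_map(smap: SimilarityMap, path: str | Path) -> Path:
    """Write a similarity map as NIfTI (missing = NaN) + a JSON sidecar."""
    from . import __version__

    path = Path(path)
    nib.save(nib.Nifti1Image(smap.data.astype(np.float32), smap.affine), str(path))
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
    sidecar = Path(str(sidecar) + ".json")
    meta = {
        "subject_id": smap.subject_id,
        "seed_stats": {
            "m": smap.seed_stats.m,
            "sigma": smap.seed_stats.sigma,
            "n_voxels": smap.seed_stats.n_voxels,
        },
        "searchlight": {
            "radius_mm": smap.spec.radius_mm,
            "min_voxels": smap.spec.min_voxels,
        },
        "software_version": __version__,
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return path
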