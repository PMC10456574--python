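"""Synthetic PET-like cohorts with known ground truth.

The generator emulates the statistical structure the connectivity analysis
assumes: spatially smooth metabolic volumes on a shared grid, a spherical
seed region, a spherical target region whose mean intensity is coupled to
a non-negative symptom score, and participant nuisance variables (age,
sex, head-motion summary).

Each volume is

    baseline + smoothed noise + score-coupled target offset,

where the noise is white Gaussian noise filtered to a chosen FWHM
(periodic boundaries, so the field is stationary and the per-voxel SD is
exactly ``noise_sd``), and the offset inside the target sphere equals
``coupling_slope × score``.  Anchoring the offset at the score floor of
zero (rather than at the cohort mean) makes the seed–target similarity a
monotone function of the score, so a negative slope yields the intended
negative score–connectivity association; a slope of zero is an exact null.

Ground truth (target mask, slope, RNG seed) rides along with every cohort
so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter

from .io import BinaryMask, MetabolicVolume, save_mask, save_volume

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticCohort",
    "sphere_mask",
    "generate_volume",
    "generate_cohort",
    "write_cohort",
]

#: FWHM of a Gaussian = sigma × 2 sqrt(2 ln 2)
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: baseline mean metabolic intensity (arbitrary image units)
BASELINE_MEAN = 100.0

#: volumes are clipped to this positive floor (uptake is non-negative)
POSITIVE_FLOOR = 1e-6 * BASELINE_MEAN


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of one simulated cohort.

    Defaults mirror the study design this generator emulates: 27 subjects
    aged 18–23 with a ~20/27 female split, 3 mm isotropic voxels, a
    non-negative symptom score (truncated normal, mean ≈ 9.1, sd ≈ 8.3 —
    the pooled moments of the cohort's printed per-sex summaries), ~5%
    voxelwise noise on the baseline, and a strong negative seed–target
    coupling whose planted peak effect matches the magnitude such studies
    report (voxelwise |r| ≈ 0.7).  Spatial smoothness defaults to 4 mm
    FWHM — below typical PET effective smoothness — so that on a small
    16³ grid the seed and searchlight regions still contain several
    independent noise samples, the regime the similarity statistic is
    designed for (real maps have hundreds of voxels per region); see the
    methods note.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_size_mm: float = 3.0
    n_subjects: int = 27
    smoothness_fwhm_mm: float = 4.0
    seed_center_mm: tuple[float, float, float] = (-10.5, 0.0, 0.0)
    seed_radius_mm: float = 6.0
    target_center_mm: tuple[float, float, float] = (10.5, 0.0, 0.0)
    target_radius_mm: float = 9.0
    coupling_slope: float = -1.0
    noise_sd: float = 5.0
    score_mean: float = 9.1
    score_sd: float = 8.3
    female_probability: float = 20.0 / 27.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        numeric = {
            "voxel_size_mm": self.voxel_size_mm,
            "smoothness_fwhm_mm": self.smoothness_fwhm_mm,
            "seed_radius_mm": self.seed_radius_mm,
            "target_radius_mm": self.target_radius_mm,
            "coupling_slope": self.coupling_slope,
            "noise_sd": self.noise_sd,
            "score_mean": self.score_mean,
            "score_sd": self.score_sd,
            "female_probability": self.female_probability,
        }
        for name, value in numeric.items():
            if not np.isfinite(value):
                raise ValueError(f"non-finite value for field {name!r}")
        for name, coords in (
            ("seed_center_mm", self.seed_center_mm),
            ("target_center_mm", self.target_center_mm),
        ):
            if not np.all(np.isfinite(coords)):
                raise ValueError(f"non-finite value for field {name!r}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.smoothness_fwhm_mm < 0:
            raise ValueError("smoothness_fwhm_mm must be non-negative")
        if any(s < 8 for s in self.grid_shape):
            raise ValueError("grid_shape must be >= 8 along every axis")
        if self.n_subjects < 8:
            raise ValueError("n_subjects must be >= 8 (residual df for 5 regressors)")
        if not (0.0 <= self.female_probability <= 1.0):
            raise ValueError("female_probability must be in [0, 1]")
        self._check_spheres()

    def _check_spheres(self) -> None:
        half = (np.asarray(self.grid_shape) - 1) / 2.0 * self.voxel_size_mm
        for name, center, radius in (
            ("seed", self.seed_center_mm, self.seed_radius_mm),
            ("target", self.target_center_mm, self.target_radius_mm),
        ):
            c = np.asarray(center)
            if np.any(np.abs(c) + radius > half + 1e-9):
                raise ValueError(f"{name} sphere does not fit inside the grid")
        gap = np.linalg.norm(
            np.asarray(self.seed_center_mm) - np.asarray(self.target_center_mm)
        )
        if gap <= self.seed_radius_mm + self.target_radius_mm:
            raise ValueError("seed and target spheres overlap")

    @property
    def affine(self) -> np.ndarray:
        """Isotropic scaling affine centring the grid on the mm origin."""
        aff = np.eye(4)
        aff[:3, :3] *= self.voxel_size_mm
        aff[:3, 3] = -(np.asarray(self.grid_shape) - 1) / 2.0 * self.voxel_size_mm
        return aff


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: where, how strongly, and from which seed."""

    target_mask: BinaryMask
    seed_mask: BinaryMask
    coupling_slope: float
    rng_seed: int


@dataclass
class SyntheticCohort:
    volumes: list[MetabolicVolume]
    participants: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig = field(repr=False, default=None)


def sphere_mask(
    center_mm: tuple[float, float, float],
    radius_mm: float,
    shape: tuple[int, int, int],
    affine: np.ndarray,
    label: str = "sphere",
) -> BinaryMask:
    """Boolean mask of voxels whose centres lie within radius of a point."""
    idx = np.indices(shape).reshape(3, -1).T
    import nibabel as nib

    mm = nib.affines.apply_affine(affine, idx)
    dist = np.linalg.norm(mm - np.asarray(center_mm), axis=1)
    data = (dist <= radius_mm + 1e-9).reshape(shape)
    return BinaryMask(data=data, affine=np.asarray(affine), label=label)


def _smoothing_norm(shape: tuple[int, int, int], sigma_vox: float) -> float:
    """SD of white noise after periodic Gaussian filtering (exact)."""
    impulse = np.zeros(shape)
    impulse[tuple(s // 2 for s in shape)] = 1.0
    kernel = gaussian_filter(impulse, sigma_vox, mode="wrap")
    return float(np.sqrt((kernel**2).sum()))


def generate_volume(
    config: SimulationConfig,
    subject_score: float,
    per_subject_rng: np.random.Generator,
    subject_id: str = "",
) -> MetabolicVolume:
    """One subject's volume: baseline + smooth noise + target offset.

    The noise field is renormalized so its per-voxel SD equals
    ``config.noise_sd`` regardless of the smoothing scale.  With both
    noise and smoothing at zero the result is the deterministic
    baseline-plus-offset field.  The volume is clipped to a small positive
    floor (metabolic uptake is physically non-negative).
    """
    if not np.isfinite(subject_score):
        raise ValueError("non-finite value for field 'subject_score'")
    shape = tuple(config.grid_shape)
    data = np.full(shape, BASELINE_MEAN)

    if config.noise_sd > 0:
        white = per_subject_rng.standard_normal(shape)
        if config.smoothness_fwhm_mm > 0:
            sigma_vox = config.smoothness_fwhm_mm / FWHM_PER_SIGMA / config.voxel_size_mm
            smooth = gaussian_filter(white, sigma_vox, mode="wrap")
            smooth /= _smoothing_norm(shape, sigma_vox)
        else:
            smooth = white
        data = data + config.noise_sd * smooth

    target = sphere_mask(
        config.target_center_mm, config.target_radius_mm, shape, config.affine
    )
    data[target.data] += config.coupling_slope * subject_score

    data = np.maximum(data, POSITIVE_FLOOR)
    return MetabolicVolume(data=data, affine=config.affine, subject_id=subject_id)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a full cohort: participants table + volumes + ground truth.

    Scores are truncated-at-zero normal (symptom scales are non-negative);
    ages uniform on 18–23 years; sex Bernoulli; mean framewise
    displacement lognormal (median ≈ 0.15 mm).  Per-subject noise streams
    are spawned independently from ``config.rng_seed``, so the cohort is
    fully reproducible and any subject's volume is independent of cohort
    ordering.
    """
    n = config.n_subjects
    ss = np.random.SeedSequence(config.rng_seed)
    table_stream, *subject_streams = ss.spawn(n + 1)
    rng = np.random.default_rng(table_stream)

    if config.score_sd > 0:
        a = (0.0 - config.score_mean) / config.score_sd
        scores = stats.truncnorm.rvs(
            a, np.inf, loc=config.score_mean, scale=config.score_sd,
            size=n, random_state=rng,
        )
    else:
        scores = np.full(n, max(config.score_mean, 0.0))
    ages = rng.uniform(18.0, 23.0, size=n)
    # condition on a mixed-sex cohort (sex is a covariate downstream and the
    # emulated design always contains both levels); redraw if degenerate
    while True:
        sexes = np.where(rng.random(n) < config.female_probability, "female", "male")
        if 0.0 < config.female_probability < 1.0 and len(np.unique(sexes)) == 2:
            break
        if config.female_probability in (0.0, 1.0):
            break
    mean_fd = rng.lognormal(mean=np.log(0.15), sigma=0.4, size=n)

    participants = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
            "score": scores,
            "age": ages,
            "sex": sexes,
            "mean_fd": mean_fd,
        }
    )

    volumes = [
        generate_volume(
            config,
            subject_score=float(scores[i]),
            per_subject_rng=np.random.default_rng(subject_streams[i]),
            subject_id=participants["subject_id"].iloc[i],
        )
        for i in range(n)
    ]

    truth = GroundTruth(
        target_mask=sphere_mask(
            config.target_center_mm, config.target_radius_mm,
            tuple(config.grid_shape), config.affine, label="truth",
        ),
        seed_mask=sphere_mask(
            config.seed_center_mm, config.seed_radius_mm,
            tuple(config.grid_shape), config.affine, label="seed",
        ),
        coupling_slope=config.coupling_slope,
        rng_seed=config.rng_seed,
    )
    return SyntheticCohort(
        volumes=volumes, participants=participants, truth=truth, config=config
    )


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write a cohort to disk: NIfTI volumes + masks, TSV table, config.

    Layout: ``<outdir>/sub-XXX_pet.nii.gz``, ``participants.tsv``,
    ``truth_target_mask.nii.gz``, ``seed_mask.nii.gz``, ``config.txt``
    (plain key = value lines).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for vol in cohort.volumes:
        save_volume(vol, outdir / f"{vol.subject_id}_pet.nii.gz")
    cohort.participants.to_csv(outdir / "participants.tsv", sep="\t", index=False)
    save_mask(cohort.truth.target_mask, outdir / "truth_target_mask.nii.gz")
    save_mask(cohort.truth.seed_mask, outdir / "seed_mask.nii.gz")
    if cohort.config is not None:
        lines = []
        for key, value in vars(cohort.config).items():
            lines.append(f"{key} = {value}")
        (outdir / "config.txt").write_text("\n".join(lines) + "\n")
    return outdir
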