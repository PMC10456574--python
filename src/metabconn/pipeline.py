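"""End-to-end convenience: volumes → similarity maps → cluster table."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .connectivity import (
    SearchlightSpec,
    SimilarityMap,
    _sphere_member_table,
    default_brain_mask,
    searchlight_map,
)
from .inference import (
    ClusterRecord,
    GLMResult,
    build_design,
    permutation_cluster_fwe,
    report_cluster_table,
)
from .io import BinaryMask, MetabolicVolume, check_cohort_alignment


@dataclass
class GroupAnalysis:
    """Everything one cohort analysis produced."""

    similarity_maps: list[SimilarityMap]
    glm: GLMResult
    clusters: list[ClusterRecord]
    table: pd.DataFrame
    brain_mask: BinaryMask


def cohort_similarity_maps(
    volumes: list[MetabolicVolume],
    seed: BinaryMask,
    brain_mask: BinaryMask | None = None,
    spec: SearchlightSpec = SearchlightSpec(),
) -> tuple[list[SimilarityMap], BinaryMask]:
    """Per-subject searchlight maps, sharing one sphere-membership table.

    If no brain mask is supplied, the deterministic default (voxels
    positive in ≥90% of subjects) is derived from the volumes themselves.
    """
    if brain_mask is None:
        brain_mask = default_brain_mask(volumes)
    report = check_cohort_alignment(volumes, [seed, brain_mask])
    if not report:
        raise ValueError("cohort not aligned: " + "; ".join(report.offenders))
    table = _sphere_member_table(
        volumes[0].shape, brain_mask.data, spec, volumes[0].affine
    )
    maps = [
        searchlight_map(vol, seed, brain_mask, spec, _table=table)
        for vol in volumes
    ]
    return maps, brain_mask


def run_group_analysis(
    volumes: list[MetabolicVolume],
    participants: pd.DataFrame,
    seed: BinaryMask,
    brain_mask: BinaryMask | None = None,
    spec: SearchlightSpec = SearchlightSpec(),
    score_column: str = "score",
    covariate_columns: list[str] | None = None,
    sided: str = "negative",
    forming_p: float = 0.001,
    connectivity: int = 18,
    n_perm: int = 999,
    rng_seed: int = 0,
    alpha: float = 0.05,
) -> GroupAnalysis:
    """Full pipeline on one cohort.

    Searchlight similarity maps per subject, voxelwise OLS of those maps
    on the score with nuisance covariates, and permutation cluster-extent
    FWE at the given forming threshold.  Returns maps, GLM fit, cluster
    records and the formatted cluster table.
    """
    if covariate_columns is None:
        covariate_columns = ["age", "sex", "mean_fd"]
    maps, brain_mask = cohort_similarity_maps(volumes, seed, brain_mask, spec)
    design = build_design(participants, score_column, covariate_columns, sided=sided)
    glm, clusters = permutation_cluster_fwe(
        maps,
        design,
        forming_p=forming_p,
        connectivity=connectivity,
        n_perm=n_perm,
        rng_seed=rng_seed,
        seed_mask=seed.data,
    )
    table = report_cluster_table(clusters, df=glm.df, alpha=alpha)
    return GroupAnalysis(
        similarity_maps=maps,
        glm=glm,
        clusters=clusters,
        table=table,
        brain_mask=brain_mask,
    )
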