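"""Group-level voxelwise regression and permutation cluster-extent inference.

Per-subject similarity maps are regressed, voxel by voxel, on a symptom
score with nuisance covariates (ordinary least squares).  Supra-threshold
voxels of the score-contrast t-map are grouped into connected clusters and
each cluster's extent receives a family-wise-error-corrected p-value from
the permutation distribution of the maximum cluster size, with
Freedman–Lane handling of the nuisance covariates: the maps are first
regressed on the nuisance-only design, the residual rows are permuted,
the nuisance fit is added back, and the full model is refit.  This
exchangeability-based correction replaces parametric random-field-theory
cluster inference; reports label the method explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .connectivity import SimilarityMap
from .io import voxel_to_mm

__all__ = [
    "CohortDesign",
    "GLMResult",
    "ClusterRecord",
    "build_design",
    "fit_voxelwise_glm",
    "extract_clusters",
    "permutation_cluster_fwe",
    "report_cluster_table",
    "dice_coefficient",
]

#: cap applied to |t| when the voxel residual is exactly zero
T_CAP = 1e6

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class CohortDesign:
    """Subjects × regressors design with the contrast of interest.

    Columns are ordered (intercept, score, covariates...).  ``contrast``
    has ±1 on the score column and 0 elsewhere; ``sided`` selects the
    tested tail of the score effect ("negative", "positive" or "two").
    """

    matrix: np.ndarray
    column_names: list[str]
    contrast: np.ndarray
    subject_ids: list[str]
    sided: str = "negative"
    condition_number: float = field(default=np.nan)

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]

    @property
    def df(self) -> int:
        """Residual degrees of freedom, n − p."""
        return self.n_subjects - self.n_regressors

    def nuisance_matrix(self) -> np.ndarray:
        """Design with the score column removed (intercept + covariates)."""
        keep = self.contrast == 0
        return self.matrix[:, keep]


@dataclass
class GLMResult:
    """Voxelwise OLS fit of similarity maps on the design."""

    beta_maps: np.ndarray  # (p, i, j, k)
    t_map: np.ndarray  # (i, j, k), NaN off defined_mask
    df: int
    defined_mask: np.ndarray
    affine: np.ndarray
    design: CohortDesign
    capped_mask: np.ndarray | None = None  # zero-residual voxels with |t| capped


@dataclass
class ClusterRecord:
    """One supra-threshold cluster of the score-contrast t-map."""

    cluster_id: int
    size_voxels: int
    peak_mm: tuple[float, float, float]
    peak_t: float
    peak_index: tuple[int, int, int]
    p_fwe: float | None = None
    in_seed_voxels: int = 0
    component_breakdown: list[dict] | None = None
    member_indices: np.ndarray | None = None  # (size, 3) voxel indices


def _code_two_level(col: pd.Series, name: str) -> tuple[np.ndarray, dict]:
    levels = sorted(pd.unique(col.astype(str)))
    if len(levels) != 2:
        raise ValueError(f"column {name!r} must have exactly 2 levels, got {levels}")
    mapping = {levels[0]: 0, levels[1]: 1}
    return col.astype(str).map(mapping).to_numpy(dtype=float), mapping


def build_design(
    participants: pd.DataFrame,
    score_column: str,
    covariate_columns: list[str],
    sided: str = "negative",
    subject_column: str = "subject_id",
) -> CohortDesign:
    """Assemble the (intercept, score, covariates...) design matrix.

    Two-level string covariates (e.g. sex) are coded 0/1 by sorted level
    order — for female/male this gives female=0, male=1 — and the mapping
    is recorded in the returned object's coding log.  Rank deficiency,
    missing values and a constant score column are errors; the condition
    number of the assembled matrix is reported on the design.
    """
    if sided not in ("negative", "positive", "two"):
        raise ValueError("sided must be 'negative', 'positive' or 'two'")
    used = [score_column, *covariate_columns]
    sub = participants[used]
    if sub.isna().any().any():
        bad = [c for c in used if sub[c].isna().any()]
        raise ValueError(f"missing values in column(s) {bad}")
    n = len(participants)
    p = 1 + len(used)
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} subjects for {p} regressors, got {n}")

    score = pd.to_numeric(participants[score_column]).to_numpy(dtype=float)
    if np.ptp(score) == 0:
        raise ValueError(f"score column {score_column!r} is constant")

    columns = [np.ones(n), score]
    names = ["intercept", score_column]
    codings: dict[str, dict] = {}
    for c in covariate_columns:
        col = participants[c]
        if col.dtype == object or str(col.dtype).startswith("category"):
            coded, mapping = _code_two_level(col, c)
            codings[c] = mapping
            columns.append(coded)
        else:
            columns.append(pd.to_numeric(col).to_numpy(dtype=float))
        names.append(c)
    X = np.column_stack(columns)

    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear columns)")

    contrast = np.zeros(X.shape[1])
    contrast[1] = -1.0 if sided == "negative" else 1.0

    if subject_column in participants.columns:
        ids = participants[subject_column].astype(str).tolist()
    else:
        ids = [f"sub-{i:03d}" for i in range(n)]

    design = CohortDesign(
        matrix=X,
        column_names=names,
        contrast=contrast,
        subject_ids=ids,
        sided=sided,
        condition_number=float(np.linalg.cond(X)),
    )
    design.covariate_codings = codings  # type: ignore[attr-defined]
    return design


def _contrast_t(
    X: np.ndarray, Y: np.ndarray, contrast: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS t for one contrast, vectorized over columns of Y (n × V).

    Returns (beta (p×V), t (V,), capped (V,)).  Zero-residual voxels get
    |t| capped at T_CAP with the sign of the contrast estimate.
    """
    n, p = X.shape
    df = n - p
    pinv = np.linalg.pinv(X)
    xtx_inv = np.linalg.inv(X.T @ X)
    c_var = float(contrast @ xtx_inv @ contrast)

    beta = pinv @ Y
    resid = Y - X @ beta
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    cb = contrast @ beta
    se = np.sqrt(c_var * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cb / se
    # (near-)zero residual: guard the numerical infinity, keep the sign
    capped = ~np.isfinite(t) | (np.abs(t) > T_CAP)
    if np.any(capped):
        t = np.where(np.isnan(t), 0.0, t)  # 0/0: no effect, no residual
        t = np.clip(t, -T_CAP, T_CAP)
    return beta, t, capped


def fit_voxelwise_glm(
    maps: list[SimilarityMap], design: CohortDesign
) -> GLMResult:
    """Ordinary least squares per voxel, subjects matched by subject_id.

    A voxel enters the fit only if all subjects have a defined value there
    (listwise rule: keeps df constant and honest across the map).  The
    contrast t uses residual variance on df = n − p.
    """
    by_id = {m.subject_id: m for m in maps}
    missing = [s for s in design.subject_ids if s not in by_id]
    if missing or len(maps) != design.n_subjects:
        raise ValueError(
            f"maps do not match design rows (missing subject_ids: {missing})"
        )
    ordered = [by_id[s] for s in design.subject_ids]
    if design.df <= 0:
        raise ValueError(f"non-positive residual df ({design.df})")

    data = np.stack([m.data for m in ordered])  # (n, i, j, k)
    defined = np.all(np.isfinite(data), axis=0)
    shape = defined.shape
    Y = data[:, defined]

    # t is always reported on the +score scale (a negative association
    # reads as negative t, as in cluster peak tables); the contrast's
    # sign / `sided` choose which tail is tested downstream
    beta, t, capped = _contrast_t(design.matrix, Y, np.abs(design.contrast))

    beta_maps = np.full((design.n_regressors, *shape), np.nan)
    beta_maps[:, defined] = beta
    t_map = np.full(shape, np.nan)
    t_map[defined] = t
    capped_mask = np.zeros(shape, dtype=bool)
    capped_mask[defined] = capped

    return GLMResult(
        beta_maps=beta_maps,
        t_map=t_map,
        df=design.df,
        defined_mask=defined,
        affine=ordered[0].affine,
        design=design,
        capped_mask=capped_mask,
    )


def _forming_threshold(forming_p: float, df: int, sided: str) -> float:
    """Positive t threshold magnitude for the cluster-forming p."""
    if not (0.0 < forming_p < 1.0):
        raise ValueError("forming_p must be in (0, 1)")
    if sided == "two":
        return float(stats.t.isf(forming_p / 2.0, df))
    return float(stats.t.isf(forming_p, df))


def _supra_mask(t_map: np.ndarray, defined: np.ndarray, tstar: float, sided: str) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        if sided == "negative":
            supra = t_map <= -tstar
        elif sided == "positive":
            supra = t_map >= tstar
        else:
            supra = np.abs(t_map) >= tstar
    return supra & defined


def extract_clusters(
    t_map: np.ndarray,
    defined_mask: np.ndarray,
    forming_p: float,
    df: int,
    sided: str = "negative",
    connectivity: int = 18,
    affine: np.ndarray | None = None,
    seed_mask: np.ndarray | None = None,
) -> list[ClusterRecord]:
    """Connected supra-threshold clusters of a t-map (no p_fwe yet).

    The forming threshold is the Student quantile for ``forming_p`` at
    ``df`` (one tail, or split across both for sided="two").  Components
    are defined by 6, 18 or 26 voxel connectivity.  The cluster peak is
    the largest |t|, ties broken by lexicographically smallest index.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    if not defined_mask.any():
        raise ValueError("defined_mask is empty")
    tstar = _forming_threshold(forming_p, df, sided)
    supra = _supra_mask(t_map, defined_mask, tstar, sided)
    labels, n_comp = ndimage.label(supra, structure=_STRUCTURES[connectivity])
    records: list[ClusterRecord] = []
    for k in range(1, n_comp + 1):
        idx = np.argwhere(labels == k)
        tvals = t_map[tuple(idx.T)]
        order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], -np.abs(tvals)))
        peak_idx = tuple(int(v) for v in idx[order[0]])
        peak_t = float(t_map[peak_idx])
        peak_mm = (
            tuple(float(v) for v in voxel_to_mm(peak_idx, affine))
            if affine is not None
            else (float("nan"),) * 3
        )
        in_seed = int(seed_mask[tuple(idx.T)].sum()) if seed_mask is not None else 0
        records.append(
            ClusterRecord(
                cluster_id=k,
                size_voxels=int(len(idx)),
                peak_mm=peak_mm,
                peak_t=peak_t,
                peak_index=peak_idx,
                in_seed_voxels=in_seed,
                member_indices=idx,
            )
        )
    records.sort(key=lambda r: (-r.size_voxels, r.peak_index))
    for i, r in enumerate(records, start=1):
        r.cluster_id = i
    return records


def _max_cluster_size(
    t: np.ndarray,
    defined_flat_shape: tuple,
    defined: np.ndarray,
    tstar: float,
    sided: str,
    structure: np.ndarray,
) -> int:
    t_map = np.full(defined.shape, np.nan)
    t_map[defined] = t
    supra = _supra_mask(t_map, defined, tstar, sided)
    if not supra.any():
        return 0
    labels, n = ndimage.label(supra, structure=structure)
    return int(np.bincount(labels.ravel())[1:].max())


def permutation_cluster_fwe(
    maps: list[SimilarityMap],
    design: CohortDesign,
    forming_p: float = 0.001,
    connectivity: int = 18,
    n_perm: int = 999,
    rng_seed: int = 0,
    seed_mask: np.ndarray | None = None,
) -> tuple[GLMResult, list[ClusterRecord]]:
    """Cluster-extent FWE p-values by Freedman–Lane permutation.

    Each permutation draws a fresh shuffling of subject rows from the
    seeded stream, applies it to the nuisance-model residuals, adds the
    nuisance fit back, refits the full model, and records the maximum
    cluster size at the same forming threshold.  The FWE p-value of an
    observed cluster of size s is (1 + #{perm max size >= s}) / (n_perm+1),
    so it is never exactly zero.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    result = fit_voxelwise_glm(maps, design)
    records = extract_clusters(
        result.t_map,
        result.defined_mask,
        forming_p,
        result.df,
        design.sided,
        connectivity,
        affine=result.affine,
        seed_mask=seed_mask,
    )

    defined = result.defined_mask
    if not defined.any():
        raise ValueError("no defined voxels at the forming threshold stage")
    data = np.stack(
        [
            {m.subject_id: m for m in maps}[s].data
            for s in design.subject_ids
        ]
    )
    Y = data[:, defined]
    X = design.matrix
    Z = design.nuisance_matrix()
    gamma = np.linalg.pinv(Z) @ Y
    fitted = Z @ gamma
    resid = Y - fitted

    tstar = _forming_threshold(forming_p, result.df, design.sided)
    structure = _STRUCTURES[connectivity]
    contrast_pos = np.abs(design.contrast)  # +score scale, as in the observed fit

    rng = np.random.default_rng(rng_seed)
    n = design.n_subjects
    max_sizes = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        perm = rng.permutation(n)
        Ystar = fitted + resid[perm]
        _, t, _ = _contrast_t(X, Ystar, contrast_pos)
        max_sizes[b] = _max_cluster_size(
            t, Y.shape, defined, tstar, design.sided, structure
        )

    for rec in records:
        exceed = int(np.sum(max_sizes >= rec.size_voxels))
        rec.p_fwe = (1 + exceed) / (n_perm + 1)
    return result, records


def report_cluster_table(
    records: list[ClusterRecord],
    df: int,
    alpha: float = 0.05,
    label_volume: np.ndarray | None = None,
    label_names: dict[int, str] | None = None,
    t_map: np.ndarray | None = None,
    affine: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cluster table: size, peak mm, peak t (with df), cluster-level p_FWE.

    Rows are sorted by p_fwe then descending size.  With a label volume
    (integer anatomical parcellation on the same grid), each cluster also
    carries a per-label breakdown (label, voxel count, local peak).
    Clusters at or below ``alpha`` are flagged significant.  The inference
    method column records that p_FWE is permutation-based.
    """
    rows = []
    ordered = sorted(
        records, key=lambda r: (r.p_fwe if r.p_fwe is not None else np.inf, -r.size_voxels)
    )
    for i, rec in enumerate(ordered, start=1):
        rows.append(
            {
                "cluster": i,
                "size_voxels": rec.size_voxels,
                "peak_x_mm": rec.peak_mm[0],
                "peak_y_mm": rec.peak_mm[1],
                "peak_z_mm": rec.peak_mm[2],
                f"peak_t_df{df}": rec.peak_t,
                "p_fwe_perm": rec.p_fwe,
                "significant": (rec.p_fwe is not None and rec.p_fwe <= alpha),
                "overlaps_seed": rec.in_seed_voxels > 0,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster",
            "size_voxels",
            "peak_x_mm",
            "peak_y_mm",
            "peak_z_mm",
            f"peak_t_df{df}",
            "p_fwe_perm",
            "significant",
            "overlaps_seed",
        ],
    )
    if label_volume is not None and records:
        if t_map is None:
            raise ValueError("label breakdown requires the t_map")
        breakdowns = []
        for rec in ordered:
            breakdowns.append(
                _label_breakdown(rec, label_volume, label_names, t_map, affine)
            )
        table["labels"] = [
            "; ".join(f"{b['label']} ({b['voxel_count']})" for b in bd)
            for bd in breakdowns
        ]
        for rec, bd in zip(ordered, breakdowns):
            rec.component_breakdown = bd
    return table


def _label_breakdown(rec, label_volume, label_names, t_map, affine):
    if label_volume.shape != t_map.shape:
        raise ValueError("label volume grid does not match the t-map grid")
    members = rec.member_indices
    if members is None:
        members = np.array([rec.peak_index])
    out = []
    labels_here = label_volume[tuple(np.asarray(members).T)]
    for lab in np.unique(labels_here):
        if lab == 0:
            continue
        sel = np.asarray(members)[labels_here == lab]
        tvals = t_map[tuple(sel.T)]
        order = np.lexsort((sel[:, 2], sel[:, 1], sel[:, 0], -np.abs(tvals)))
        peak = sel[order[0]]
        out.append(
            {
                "label": label_names.get(int(lab), str(int(lab))) if label_names else str(int(lab)),
                "voxel_count": int(len(sel)),
                "local_peak_mm": (
                    tuple(float(v) for v in voxel_to_mm(peak, affine))
                    if affine is not None
                    else tuple(int(v) for v in peak)
                ),
                "local_peak_t": float(t_map[tuple(peak)]),
            }
        )
    out.sort(key=lambda d: -d["voxel_count"])
    return out


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two boolean volumes."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
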