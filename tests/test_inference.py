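import numpy as np
import pandas as pd
import pytest

import metabconn as mc
from metabconn.inference import T_CAP


def _participants(n=27, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:03d}" for i in range(n)],
            "score": rng.uniform(0, 30, n),
            "age": rng.uniform(18, 23, n),
            "sex": rng.choice(["female", "male"], n),
            "mean_fd": rng.lognormal(np.log(0.15), 0.4, n),
        }
    )


def _maps_from_array(data, affine=None, ids=None):
    """Wrap an (n, i, j, k) array as SimilarityMap objects."""
    n = data.shape[0]
    affine = np.eye(4) if affine is None else affine
    ids = ids or [f"sub-{i:03d}" for i in range(n)]
    seed_stats = mc.RegionStats(m=1.0, sigma=1.0, n_voxels=4)
    return [
        mc.SimilarityMap(
            data=data[i], affine=affine, subject_id=ids[i],
            seed_stats=seed_stats, spec=mc.SearchlightSpec(),
        )
        for i in range(n)
    ]


class TestBuildDesign:
    def test_study_sized_design_has_df_22(self):
        design = mc.build_design(_participants(27), "score", ["age", "sex", "mean_fd"])
        assert design.n_regressors == 5
        assert design.df == 22
        assert design.column_names == ["intercept", "score", "age", "sex", "mean_fd"]
        assert np.isfinite(design.condition_number)

    def test_duplicate_covariate_is_rank_deficient(self):
        df = _participants(20)
        df["age2"] = df["age"]
        with pytest.raises(ValueError, match="rank deficient"):
            mc.build_design(df, "score", ["age", "age2"])

    def test_input_column_order_is_irrelevant(self):
        df = _participants(15)
        shuffled = df[["mean_fd", "sex", "subject_id", "age", "score"]]
        a = mc.build_design(df, "score", ["age", "sex", "mean_fd"])
        b = mc.build_design(shuffled, "score", ["age", "sex", "mean_fd"])
        np.testing.assert_array_equal(a.matrix, b.matrix)
        assert a.column_names == b.column_names

    def test_sex_coded_by_sorted_level_order(self):
        df = _participants(12, seed=3)
        design = mc.build_design(df, "score", ["sex"])
        assert design.covariate_codings["sex"] == {"female": 0, "male": 1}

    def test_missing_values_rejected(self):
        df = _participants(12)
        df.loc[3, "age"] = np.nan
        with pytest.raises(ValueError, match="missing values"):
            mc.build_design(df, "score", ["age"])

    def test_constant_score_rejected(self):
        df = _participants(12)
        df["score"] = 5.0
        with pytest.raises(ValueError, match="constant"):
            mc.build_design(df, "score", ["age"])


class TestVoxelwiseGLM:
    def test_matches_normal_equations_oracle(self):
        """10-subject, 4-voxel fixture against explicit (X'X)^-1 X'y."""
        rng = np.random.default_rng(42)
        df = _participants(10, seed=1)
        design = mc.build_design(df, "score", ["age", "sex", "mean_fd"])
        data = rng.uniform(0.2, 0.9, size=(10, 2, 2, 1))
        maps = _maps_from_array(data, ids=df["subject_id"].tolist())
        res = mc.fit_voxelwise_glm(maps, design)

        X = design.matrix
        c = np.abs(design.contrast)
        for v in np.ndindex(2, 2, 1):
            y = data[(slice(None), *v)]
            beta = np.linalg.inv(X.T @ X) @ X.T @ y
            resid = y - X @ beta
            s2 = resid @ resid / res.df
            t = (c @ beta) / np.sqrt(s2 * c @ np.linalg.inv(X.T @ X) @ c)
            np.testing.assert_allclose(res.beta_maps[(slice(None), *v)], beta, atol=1e-10)
            np.testing.assert_allclose(res.t_map[v], t, atol=1e-10)

    def test_zero_residual_t_is_capped_and_flagged(self):
        df = _participants(10, seed=2)
        design = mc.build_design(df, "score", ["age", "sex", "mean_fd"])
        score = design.matrix[:, 1]
        data = (0.01 * score)[:, None, None, None] * np.ones((10, 2, 2, 1))
        res = mc.fit_voxelwise_glm(
            _maps_from_array(data, ids=df["subject_id"].tolist()), design
        )
        assert np.all(np.abs(res.t_map) == T_CAP)
        assert res.capped_mask.all()

    def test_permuting_scores_destroys_signal(self):
        rng = np.random.default_rng(7)
        df = _participants(24, seed=5)
        design = mc.build_design(df, "score", ["age", "sex", "mean_fd"])
        score = design.matrix[:, 1]
        data = score[:, None, None, None] * np.ones((24, 3, 3, 3))
        data += rng.normal(0, 2.0, data.shape)
        maps = _maps_from_array(data, ids=df["subject_id"].tolist())
        t_signal = np.abs(mc.fit_voxelwise_glm(maps, design).t_map).mean()

        df_perm = df.copy()
        df_perm["score"] = rng.permutation(df["score"].to_numpy())
        design_perm = mc.build_design(df_perm, "score", ["age", "sex", "mean_fd"])
        t_null = np.abs(mc.fit_voxelwise_glm(maps, design_perm).t_map).mean()
        assert t_null < t_signal / 2

    def test_listwise_voxel_exclusion(self):
        df = _participants(10, seed=9)
        design = mc.build_design(df, "score", ["age", "sex", "mean_fd"])
        data = np.random.default_rng(0).uniform(0, 1, (10, 2, 2, 2))
        data[3, 0, 0, 0] = np.nan
        res = mc.fit_voxelwise_glm(
            _maps_from_array(data, ids=df["subject_id"].tolist()), design
        )
        assert not res.defined_mask[0, 0, 0]
        assert np.isnan(res.t_map[0, 0, 0])
        assert res.defined_mask.sum() == 7

    def test_subject_mismatch_is_an_error(self):
        df = _participants(10)
        design = mc.build_design(df, "score", ["age", "sex", "mean_fd"])
        maps = _maps_from_array(np.zeros((10, 2, 2, 1)), ids=[f"x{i}" for i in range(10)])
        with pytest.raises(ValueError, match="subject_id"):
            mc.fit_voxelwise_glm(maps, design)

    def test_nuisance_shift_invariance(self):
        """Adding a constant to age must not change the score t-map."""
        df = _participants(20, seed=11)
        data = np.random.default_rng(1).uniform(0, 1, (20, 3, 3, 2))
        maps = _maps_from_array(data, ids=df["subject_id"].tolist())
        a = mc.fit_voxelwise_glm(
            maps, mc.build_design(df, "score", ["age", "sex", "mean_fd"])
        )
        df2 = df.copy()
        df2["age"] = df2["age"] + 100.0
        b = mc.fit_voxelwise_glm(
            maps, mc.build_design(df2, "score", ["age", "sex", "mean_fd"])
        )
        np.testing.assert_allclose(a.t_map, b.t_map, atol=1e-9)


def _flood_fill_components(mask, neighbours):
    """Brute-force connected components by breadth-first flood fill."""
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for start in np.argwhere(mask):
        start = tuple(start)
        if seen[start]:
            continue
        comp, queue = [], [start]
        seen[start] = True
        while queue:
            v = queue.pop()
            comp.append(v)
            for off in neighbours:
                w = tuple(np.array(v) + off)
                if all(0 <= w[d] < mask.shape[d] for d in range(3)):
                    if mask[w] and not seen[w]:
                        seen[w] = True
                        queue.append(w)
        comps.append(sorted(comp))
    return sorted(comps)


def _neighbour_offsets(connectivity):
    out = []
    for o in np.ndindex(3, 3, 3):
        d = np.array(o) - 1
        nonzero = np.count_nonzero(d)
        if nonzero == 0:
            continue
        if (connectivity == 6 and nonzero == 1) or \
           (connectivity == 18 and nonzero <= 2) or connectivity == 26:
            out.append(d)
    return out


class TestExtractClusters:
    def _tmap(self, shape=(8, 8, 8)):
        return np.zeros(shape), np.ones(shape, dtype=bool)

    def test_no_suprathreshold_voxels_gives_empty_list(self):
        t, defined = self._tmap()
        assert mc.extract_clusters(t, defined, 0.001, df=22) == []

    def test_two_separated_blobs_connectivity_6(self):
        t, defined = self._tmap()
        t[1, 1, 1:4] = -10.0
        t[6, 6, 3:6] = -10.0
        recs = mc.extract_clusters(t, defined, 0.001, df=22, connectivity=6)
        assert sorted(r.size_voxels for r in recs) == [3, 3]

    def test_diagonal_blobs_merge_at_26_split_at_6(self):
        t, defined = self._tmap()
        t[2, 2, 2] = -10.0
        t[3, 3, 3] = -10.0  # corner-touching
        at6 = mc.extract_clusters(t, defined, 0.001, df=22, connectivity=6)
        at26 = mc.extract_clusters(t, defined, 0.001, df=22, connectivity=26)
        assert len(at6) == 2 and len(at26) == 1

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(13)
        t = np.where(rng.random((7, 7, 7)) < 0.2, -10.0, 0.0)
        defined = np.ones_like(t, dtype=bool)
        recs = mc.extract_clusters(t, defined, 0.001, df=22, connectivity=connectivity)
        oracle = _flood_fill_components(t < 0, _neighbour_offsets(connectivity))
        got = sorted(
            sorted(tuple(v) for v in r.member_indices) for r in recs
        )
        assert got == oracle

    def test_stricter_forming_threshold_never_grows_clusters(self):
        rng = np.random.default_rng(17)
        t = rng.normal(0, 2, (10, 10, 10))
        defined = np.ones_like(t, dtype=bool)
        lax = mc.extract_clusters(t, defined, 0.01, df=22)
        strict = mc.extract_clusters(t, defined, 0.001, df=22)
        assert sum(r.size_voxels for r in strict) <= sum(r.size_voxels for r in lax)
        assert (max((r.size_voxels for r in strict), default=0)
                <= max((r.size_voxels for r in lax), default=0))

    def test_peak_is_largest_magnitude_then_smallest_index(self):
        t, defined = self._tmap()
        t[4, 4, 4] = t[4, 4, 5] = -8.0
        t[4, 4, 6] = -5.0
        recs = mc.extract_clusters(t, defined, 0.001, df=22)
        assert recs[0].peak_index == (4, 4, 4)
        assert recs[0].peak_t == -8.0

    def test_positive_and_two_sided_tails(self):
        t, defined = self._tmap()
        t[1, 1, 1] = 8.0
        t[5, 5, 5] = -8.0
        pos = mc.extract_clusters(t, defined, 0.001, df=22, sided="positive")
        two = mc.extract_clusters(t, defined, 0.001, df=22, sided="two")
        assert len(pos) == 1 and pos[0].peak_t == 8.0
        assert len(two) == 2


class TestPermutationFWE:
    def _strong_cohort(self):
        cfg = mc.SimulationConfig(grid_shape=(10, 10, 10), n_subjects=20,
                                  seed_center_mm=(-7.5, 0.0, 0.0), seed_radius_mm=4.5,
                                  target_center_mm=(7.5, 0.0, 0.0), target_radius_mm=6.0,
                                  rng_seed=77)
        return mc.generate_cohort(cfg)

    def test_counting_formula_floor(self):
        """Cluster beating all 999 permutation maxima gets p exactly 1/1000.

        Constructed fixture: a 3-cube block whose values follow the score
        almost exactly, so the observed cluster dwarfs anything a
        permutation can produce.
        """
        rng = np.random.default_rng(8)
        df = _participants(16, seed=8)
        score = df["score"].to_numpy()
        data = rng.normal(0.5, 0.01, size=(16, 6, 6, 6))
        data[:, 1:4, 1:4, 1:4] -= 0.02 * score[:, None, None, None]
        maps = _maps_from_array(data, ids=df["subject_id"].tolist())
        design = mc.build_design(df, "score", ["age", "sex", "mean_fd"])
        _, recs = mc.permutation_cluster_fwe(maps, design, forming_p=0.001,
                                             n_perm=999, rng_seed=3)
        assert recs, "expected the planted cluster to be detected"
        top = min(recs, key=lambda r: r.p_fwe)
        assert top.size_voxels == 27
        assert top.p_fwe == pytest.approx(1.0 / 1000.0)

    def test_seeded_stream_is_deterministic(self):
        co = self._strong_cohort()
        maps, _ = mc.cohort_similarity_maps(co.volumes, co.truth.seed_mask)
        design = mc.build_design(co.participants, "score", ["age", "sex", "mean_fd"])
        _, a = mc.permutation_cluster_fwe(maps, design, n_perm=120, rng_seed=9)
        _, b = mc.permutation_cluster_fwe(maps, design, n_perm=120, rng_seed=9)
        assert [r.p_fwe for r in a] == [r.p_fwe for r in b]

    def test_too_few_permutations_rejected(self):
        co = self._strong_cohort()
        maps, _ = mc.cohort_similarity_maps(co.volumes, co.truth.seed_mask)
        design = mc.build_design(co.participants, "score", ["age", "sex", "mean_fd"])
        with pytest.raises(ValueError, match="n_perm"):
            mc.permutation_cluster_fwe(maps, design, n_perm=10, rng_seed=0)

    def test_null_pvalues_are_valid(self, null_calibration):
        """Under the null, P(p_fwe <= a) <= a plus binomial error."""
        n = len(null_calibration)
        for alpha in (0.01, 0.05):
            rate = float(np.mean(null_calibration <= alpha))
            bound = alpha + 2.0 * np.sqrt(alpha * (1 - alpha) / n)
            assert rate <= bound


class TestClusterTable:
    def _rec(self, cid, size, p, t=-5.0, idx=(1, 1, 1)):
        return mc.ClusterRecord(
            cluster_id=cid, size_voxels=size, peak_mm=(3.0, 6.0, 9.0),
            peak_t=t, peak_index=idx, p_fwe=p,
            member_indices=np.array([idx]),
        )

    def test_empty_records_give_header_only(self):
        table = mc.report_cluster_table([], df=22)
        assert len(table) == 0
        assert "p_fwe_perm" in table.columns
        assert "peak_t_df22" in table.columns

    def test_paper_style_row_formatting(self):
        table = mc.report_cluster_table([self._rec(1, 974, 0.008)], df=22)
        assert table.loc[0, "size_voxels"] == 974
        assert table.loc[0, "p_fwe_perm"] == pytest.approx(0.008)
        assert bool(table.loc[0, "significant"])

    def test_equal_p_orders_by_descending_size(self):
        recs = [self._rec(1, 10, 0.02), self._rec(2, 40, 0.02)]
        table = mc.report_cluster_table(recs, df=22)
        assert list(table["size_voxels"]) == [40, 10]

    def test_label_breakdown(self):
        rec = mc.ClusterRecord(
            cluster_id=1, size_voxels=3, peak_mm=(0.0, 0.0, 0.0),
            peak_t=-6.0, peak_index=(1, 1, 1), p_fwe=0.01,
            member_indices=np.array([(1, 1, 1), (1, 1, 2), (1, 2, 1)]),
        )
        labels = np.zeros((4, 4, 4), dtype=int)
        labels[1, 1, :] = 1
        labels[1, 2, 1] = 2
        t_map = np.zeros((4, 4, 4))
        t_map[1, 1, 1] = -6.0
        table = mc.report_cluster_table(
            [rec], df=22, label_volume=labels,
            label_names={1: "regionA", 2: "regionB"}, t_map=t_map,
        )
        assert "regionA (2)" in table.loc[0, "labels"]
        assert rec.component_breakdown[0]["label"] == "regionA"
        assert rec.component_breakdown[0]["local_peak_t"] == -6.0


def test_dice_coefficient_known_values():
    a = np.zeros((3, 3, 3), dtype=bool)
    b = np.zeros((3, 3, 3), dtype=bool)
    a[0, 0, :2] = True
    b[0, 0, 1:3] = True
    assert mc.dice_coefficient(a, b) == pytest.approx(0.5)
    assert mc.dice_coefficient(a, a) == 1.0
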