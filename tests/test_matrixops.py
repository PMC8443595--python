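"""Significance matrices, scaling, SVD-impute PCA and UPGMA clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from seednet.enrichment import ContingencyCounts, EnrichmentResult
from seednet.matrixops import (
    Dendrogram,
    build_significance_matrix,
    cluster_upgma_pearson,
    filter_missing,
    pca_svd_impute,
    pearson_distance_matrix,
    scale_unit_variance,
    upgma,
    zscore_matrix,
)


def _res(region: str, p: float) -> EnrichmentResult:
    return EnrichmentResult(
        query_label="q",
        set_label=region,
        counts=ContingencyCounts(1, 2, 3, 10),
        p_value=p,
        enrichment_ratio=1.0,
        overlap_genes=["g"],
    )


def brute_force_upgma(dist: pd.DataFrame) -> list:
    """Oracle: clusters as label sets; distance = mean over all cross pairs
    of the *original* matrix (no incremental update)."""
    labels = list(dist.index)
    clusters = {i: frozenset([labels[i]]) for i in range(len(labels))}
    merges = []
    next_id = len(labels)
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            d = float(
                np.mean(
                    [dist.loc[a, b] for a in clusters[i] for b in clusters[j]]
                )
            )
            key = (d, min(min(clusters[i]), min(clusters[j])),
                   max(min(clusters[i]), min(clusters[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        (d, _, _), i, j = best
        merges.append((i, j, d, next_id))
        clusters[next_id] = clusters.pop(i) | clusters.pop(j)
        next_id += 1
    return merges


class TestBuildSignificanceMatrix:
    def test_log_transform_values(self):
        m = build_significance_matrix({"c1": [_res("r1", 1.0), _res("r2", 0.05)]})
        assert m.loc["r1", "c1"] == 0.0
        assert m.loc["r2", "c1"] == pytest.approx(1.3010, abs=1e-4)

    def test_absent_pair_is_missing(self):
        m = build_significance_matrix(
            {"c1": [_res("r1", 0.5)], "c2": [_res("r2", 0.5)]}
        )
        assert np.isnan(m.loc["r2", "c1"])
        assert np.isnan(m.loc["r1", "c2"])

    def test_zero_p_is_floored(self):
        m = build_significance_matrix({"c1": [_res("r1", 0.0)]})
        assert m.loc["r1", "c1"] == pytest.approx(300.0)

    def test_duplicate_cell_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_significance_matrix({"c1": [_res("r1", 0.5), _res("r1", 0.6)]})


class TestFilterMissing:
    def test_complete_matrix_unchanged(self):
        m = pd.DataFrame(np.ones((3, 3)))
        pd.testing.assert_frame_equal(filter_missing(m, 0.7), m)

    def test_boundary_is_strict(self):
        # 7 of 10 cells missing == 0.70 -> dropped ("less than 70%" kept)
        row = [1.0] * 3 + [np.nan] * 7
        m = pd.DataFrame([row, [1.0] * 10], index=["bad", "good"])
        with pytest.warns(UserWarning):
            out = filter_missing(m, 0.70)
        assert list(out.index) == ["good"]

    def test_column_dropped_after_rows(self):
        m = pd.DataFrame(
            {"a": [1.0, 1.0, 1.0], "b": [np.nan, np.nan, 1.0], "c": [1.0, 1.0, 1.0]}
        )
        with pytest.warns(UserWarning):
            out = filter_missing(m, 0.5)
        assert list(out.columns) == ["a", "c"]

    def test_all_dropped_is_error(self):
        m = pd.DataFrame({"a": [np.nan, np.nan]})
        with pytest.raises(ValueError):
            filter_missing(m, 0.5)


class TestScaling:
    def test_simple_row(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["r"])
        out = scale_unit_variance(m, axis="rows")
        np.testing.assert_allclose(out.loc["r"], [-1.0, 0.0, 1.0])

    def test_constant_row_dropped(self):
        m = pd.DataFrame([[1.0, 1.0], [1.0, 2.0]], index=["const", "ok"])
        with pytest.warns(UserWarning, match="constant"):
            out = scale_unit_variance(m)
        assert list(out.index) == ["ok"]

    def test_row_variances_are_one(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 4)))
        out = scale_unit_variance(m, axis="rows")
        np.testing.assert_allclose(out.var(axis=1, ddof=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)

    def test_missing_stays_missing(self):
        m = pd.DataFrame([[1.0, np.nan, 3.0, 5.0]])
        out = scale_unit_variance(m)
        assert np.isnan(out.iloc[0, 1])

    def test_columns_axis(self, rng):
        m = pd.DataFrame(rng.normal(size=(4, 3)))
        out = scale_unit_variance(m, axis="columns")
        np.testing.assert_allclose(out.var(axis=0, ddof=1), 1.0, atol=1e-12)


class TestZScore:
    def test_simple_row(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(zscore_matrix(m).iloc[0], [-1.0, 0.0, 1.0])

    def test_constant_row_becomes_zeros(self):
        m = pd.DataFrame([[2.0, 2.0, 2.0]])
        with pytest.warns(UserWarning, match="constant"):
            out = zscore_matrix(m)
        np.testing.assert_allclose(out.iloc[0], 0.0)

    def test_mean_zero_sd_one_per_axis(self, rng):
        m = pd.DataFrame(rng.normal(size=(6, 5)))
        out = zscore_matrix(m, axis="columns")
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_shape_preserved_with_missing(self):
        m = pd.DataFrame([[1.0, np.nan, 3.0], [4.0, 5.0, 6.0]])
        out = zscore_matrix(m)
        assert out.shape == m.shape
        assert np.isnan(out.iloc[0, 1])


class TestPCA:
    def test_complete_matrix_equals_direct_svd(self, rng):
        X = rng.normal(size=(6, 5))
        m = pd.DataFrame(X)
        res = pca_svd_impute(m, n_components=3)
        assert res.n_iterations == 1 and res.converged
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        expected_scores = (Vt[:3].T * s[:3])
        # singular vectors are sign-ambiguous: compare up to per-component sign
        for c in range(3):
            got = res.scores.iloc[:, c].to_numpy()
            assert (
                np.allclose(got, expected_scores[:, c], atol=1e-10)
                or np.allclose(got, -expected_scores[:, c], atol=1e-10)
            )
        np.testing.assert_allclose(
            res.variance_explained, 100 * s[:3] ** 2 / np.sum(s**2), atol=1e-10
        )

    def test_variance_sums_to_100_on_complete_matrix(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 4)))
        res = pca_svd_impute(m, n_components=4)
        assert np.sum(res.variance_explained) == pytest.approx(100.0, abs=1e-6)
        assert np.all(np.diff(res.variance_explained) <= 1e-9)

    def test_scores_orthogonal_on_complete_matrix(self, rng):
        m = pd.DataFrame(rng.normal(size=(7, 6)))
        res = pca_svd_impute(m, n_components=4)
        S = res.scores.to_numpy()
        gram = S.T @ S
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_rank1_matrix_recovered_through_deletion(self, rng):
        u = rng.normal(size=10)
        v = rng.normal(size=8)
        X = np.outer(u, v)
        mask = rng.random(X.shape) < 0.10
        Xm = X.copy()
        Xm[mask] = np.nan
        res = pca_svd_impute(pd.DataFrame(Xm), n_components=1, tol=1e-9)
        assert res.variance_explained[0] >= 99.9
        np.testing.assert_allclose(
            res.completed.to_numpy()[mask], X[mask], atol=1e-6
        )

    def test_loadings_are_correlations(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 6)))
        res = pca_svd_impute(m, n_components=2)
        for i in range(5):
            r = np.corrcoef(m.iloc[i], res.scores.iloc[:, 0])[0, 1]
            assert res.loadings.iloc[i, 0] == pytest.approx(r, abs=1e-10)
        assert np.all(np.abs(res.loadings.to_numpy()) <= 1 + 1e-9)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_svd_impute(pd.DataFrame(rng.normal(size=(3, 3))), n_components=4)


class TestUPGMA:
    def test_duplicated_column_merges_first_at_zero(self, rng):
        base = rng.normal(size=5)
        m = pd.DataFrame(
            {"a": base, "b": base, "c": rng.normal(size=5), "d": rng.normal(size=5)}
        )
        dend = cluster_upgma_pearson(m, axis="columns")
        a, b, h, _ = dend.merges[0]
        assert {dend.labels[a], dend.labels[b]} == {"a", "b"}
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_distance_two(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [3.0, 2.0, 1.0]})
        d = pearson_distance_matrix(m, axis="columns")
        assert d.loc["a", "b"] == pytest.approx(2.0)

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(15):
            n = int(rng.integers(3, 7))
            raw = rng.random((n, n))
            dist = (raw + raw.T) / 2
            np.fill_diagonal(dist, 0.0)
            labels = [f"L{i}" for i in range(n)]
            df = pd.DataFrame(dist, index=labels, columns=labels)
            got = upgma(df).merges
            expected = brute_force_upgma(df)
            for (a, b, h, new), (ea, eb, eh, enew) in zip(got, expected):
                assert {a, b} == {ea, eb}
                assert new == enew
                assert h == pytest.approx(eh, abs=1e-10)

    def test_heights_monotone(self, rng):
        raw = rng.random((8, 8))
        dist = (raw + raw.T) / 2
        np.fill_diagonal(dist, 0.0)
        labels = [f"L{i}" for i in range(8)]
        dend = upgma(pd.DataFrame(dist, index=labels, columns=labels))
        heights = [h for _, _, h, _ in dend.merges]
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_invariant_under_column_permutation(self, rng):
        m = pd.DataFrame(
            rng.normal(size=(6, 5)), columns=["e", "c", "a", "d", "b"]
        )
        d1 = cluster_upgma_pearson(m, axis="columns")
        d2 = cluster_upgma_pearson(m[sorted(m.columns)], axis="columns")
        mem1 = sorted(
            tuple(sorted({d1.labels[i] for i in s})) for s in d1.members().values()
        )
        mem2 = sorted(
            tuple(sorted({d2.labels[i] for i in s})) for s in d2.members().values()
        )
        assert mem1 == mem2
        h1 = sorted(h for _, _, h, _ in d1.merges)
        h2 = sorted(h for _, _, h, _ in d2.merges)
        np.testing.assert_allclose(h1, h2, atol=1e-12)

    def test_tie_break_is_lexicographic(self):
        # equidistant triangle: first merge must involve the two smallest labels
        labels = ["b", "c", "a"]
        dist = pd.DataFrame(
            [[0.0, 1.0, 1.0], [1.0, 0.0, 1.0], [1.0, 1.0, 0.0]],
            index=labels,
            columns=labels,
        )
        dend = upgma(dist)
        a, b, _, _ = dend.merges[0]
        assert {dend.labels[a], dend.labels[b]} == {"a", "b"}

    def test_constant_vector_error_names_vector(self):
        m = pd.DataFrame({"flat": [1.0, 1.0, 1.0], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            cluster_upgma_pearson(m, axis="columns")

    def test_matches_scipy_average_linkage(self, rng):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        raw = rng.random((7, 7))
        dist = (raw + raw.T) / 2
        np.fill_diagonal(dist, 0.0)
        labels = [f"L{i}" for i in range(7)]
        dend = upgma(pd.DataFrame(dist, index=labels, columns=labels))
        Z = linkage(squareform(dist), method="average")
        np.testing.assert_allclose(
            sorted(h for _, _, h, _ in dend.merges), sorted(Z[:, 2]), atol=1e-10
        )

    def test_newick_parses_and_is_ultrametric(self, rng):
        import io

        import skbio

        m = pd.DataFrame(rng.normal(size=(6, 4)), columns=list("abcd"))
        dend = cluster_upgma_pearson(m, axis="columns")
        tree = skbio.TreeNode.read(io.StringIO(dend.to_newick()))
        depths = {t.name: t.accumulate_to_ancestor(tree) for t in tree.tips()}
        assert set(depths) == set("abcd")
        root_h = dend.merges[-1][2]
        for d in depths.values():
            assert d == pytest.approx(root_h / 2, abs=1e-9)

    def test_cut_partitions(self, rng):
        m = pd.DataFrame(rng.normal(size=(6, 5)), columns=list("abcde"))
        dend = cluster_upgma_pearson(m, axis="columns")
        for k in range(1, 6):
            parts = dend.cut(k)
            assert len(parts) == k
            assert set().union(*parts) == set("abcde")
        with pytest.raises(ValueError):
            dend.cut(0)
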