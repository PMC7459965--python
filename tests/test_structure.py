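"""Row scaling, Euclidean agglomeration, and SVD-with-imputation PCA."""

import io as _io

import numpy as np
import pytest
from Bio import Phylo

import oracles
from gynoscreen import (
    analyze_structure,
    hierarchical_cluster,
    pca_svd_impute,
    scale_rows,
)
from gynoscreen.errors import DataError, UsageError


class TestScaleRows:
    def test_none_is_identity(self):
        X = np.array([[1.0, 2.0, 3.0]])
        out, kept = scale_rows(X, "none")
        np.testing.assert_array_equal(out, X)
        np.testing.assert_array_equal(kept, [0])

    def test_centering(self):
        out, _ = scale_rows(np.array([[1.0, 2.0, 3.0]]), "center")
        np.testing.assert_allclose(out, [[-1.0, 0.0, 1.0]])

    def test_unit_variance_rows_have_sd_one(self):
        rng = np.random.default_rng(0)
        out, kept = scale_rows(rng.normal(size=(5, 8)), "unit_variance")
        np.testing.assert_allclose(out.std(axis=1, ddof=1), np.ones(5), rtol=1e-12)
        assert len(kept) == 5

    def test_zero_variance_rows_dropped_with_warning(self):
        X = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            out, kept = scale_rows(X, "unit_variance")
        np.testing.assert_array_equal(kept, [1])
        assert out.shape == (1, 3)


class TestHierarchicalCluster:
    def test_identical_pair_merges_first_at_height_zero(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0], [0.0, 0.0]])
        d = hierarchical_cluster(X)
        a, b, h = d.merges[0]
        assert {int(a), int(b)} == {0, 2}
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_one_dimensional_points_average_linkage(self):
        d = hierarchical_cluster(np.array([[0.0], [1.0], [10.0]]), linkage="average")
        a, b, h = d.merges[0]
        assert {int(a), int(b)} == {0, 1} and h == pytest.approx(1.0)
        a, b, h = d.merges[1]
        assert {int(a), int(b)} == {2, 3}  # point 10 joins the {0,1} cluster
        assert h == pytest.approx(9.5)  # mean of distances 10 and 9

    def test_row_permutation_preserves_topology(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 3))
        perm = rng.permutation(6)
        d1 = hierarchical_cluster(X)
        d2 = hierarchical_cluster(X[perm])
        # same multiset of merge heights and same leaf partitions
        np.testing.assert_allclose(sorted(d1.merges[:, 2]), sorted(d2.merges[:, 2]))
        parts1 = {frozenset(d1.leaves_of(6 + i)) for i in range(5)}
        parts2 = {frozenset(int(perm[x]) for x in d2.leaves_of(6 + i))
                  for i in range(5)}
        assert parts1 == parts2

    @pytest.mark.parametrize("linkage", ["average", "complete", "single"])
    @pytest.mark.parametrize("seed", range(5))
    def test_merges_match_naive_agglomeration(self, linkage, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(6, 3))
        d = hierarchical_cluster(X, linkage=linkage)
        expected = oracles.agglomerate(X, method=linkage)
        for (ea, eb, eh), row in zip(expected, d.merges):
            assert {ea, eb} == {int(row[0]), int(row[1])}
            assert row[2] == pytest.approx(eh, rel=1e-9)

    def test_heights_non_decreasing_and_count(self):
        rng = np.random.default_rng(9)
        d = hierarchical_cluster(rng.normal(size=(8, 4)))
        assert len(d.merges) == 7
        assert (np.diff(d.merges[:, 2]) >= -1e-12).all()

    def test_newick_export_parses_and_preserves_leaves(self):
        rng = np.random.default_rng(2)
        labels = [f"s{i}" for i in range(6)]
        d = hierarchical_cluster(rng.normal(size=(6, 3)), labels=labels)
        tree = Phylo.read(_io.StringIO(d.to_newick()), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(labels)

    def test_single_item_rejected(self):
        with pytest.raises(UsageError):
            hierarchical_cluster(np.array([[1.0, 2.0]]))


class TestPcaSvdImpute:
    def test_rank_one_matrix_explains_everything_on_pc1(self):
        u = np.array([1.0, -1.0, 2.0, 0.0])
        v = np.array([3.0, 1.0, -2.0])
        X = np.outer(u, v)
        res = pca_svd_impute(X, n_components=2)
        assert res.explained[0] == pytest.approx(100.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_no_missing_matches_eigendecomposition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(6, 4))
        res = pca_svd_impute(X, n_components=3)
        scores_o, explained_o = oracles.pca_eig(X, 3)
        np.testing.assert_allclose(res.explained[:3], explained_o[:3], rtol=1e-9)
        for k in range(3):  # equality up to component sign
            s_pkg, s_orc = res.scores[:, k], scores_o[:, k]
            sign = np.sign(s_pkg @ s_orc)
            np.testing.assert_allclose(s_pkg, sign * s_orc, atol=1e-9)

    def test_variance_explained_sums_to_hundred(self):
        rng = np.random.default_rng(1)
        res = pca_svd_impute(rng.normal(size=(7, 5)), n_components=2)
        assert res.explained.sum() == pytest.approx(100.0, rel=1e-9)
        assert (np.diff(res.explained) <= 1e-12).all()
        assert (res.explained >= 0).all()

    def test_missing_entry_in_rank_one_matrix_recovered(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])
        v = np.array([2.0, -1.0, 0.5])
        X = np.outer(u, v)
        X_missing = X.copy()
        X_missing[2, 0] = np.nan
        res = pca_svd_impute(X_missing, n_components=1, tol=1e-10, max_iter=500)
        assert res.converged
        # the completed matrix reproduces the rank-1 pattern: scores stay rank-1
        scores_full = pca_svd_impute(X, n_components=1).scores[:, 0]
        np.testing.assert_allclose(res.scores[:, 0], scores_full, atol=1e-5)

    def test_sample_order_permutation_permutes_scores(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 4))
        perm = rng.permutation(6)
        r1 = pca_svd_impute(X, n_components=2)
        r2 = pca_svd_impute(X[perm], n_components=2)
        for k in range(2):
            a, b = r1.scores[perm, k], r2.scores[:, k]
            sign = np.sign(a @ b)
            np.testing.assert_allclose(a * sign, b, atol=1e-9)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(6)
        res = pca_svd_impute(rng.normal(size=(5, 4)), n_components=2)
        for k in range(2):
            j = np.argmax(np.abs(res.loadings[:, k]))
            assert res.loadings[j, k] > 0

    def test_all_missing_column_rejected(self):
        X = np.ones((3, 3))
        X[:, 1] = np.nan
        with pytest.raises(DataError):
            pca_svd_impute(X)

    def test_too_many_components_rejected(self):
        with pytest.raises(UsageError):
            pca_svd_impute(np.ones((3, 3)), n_components=4)


def test_analyze_structure_bundles_dendrograms_and_pca():
    rng = np.random.default_rng(12)
    values = rng.lognormal(2.0, 1.0, size=(10, 8))
    tids = [f"t{i}" for i in range(10)]
    sids = [f"s{j}" for j in range(8)]
    st = analyze_structure(values, tids, sids)
    assert st.sample_dendrogram.n_leaves == 8
    assert st.transcript_dendrogram.n_leaves == 10
    assert st.pca.scores.shape == (8, 2)
    meta = st.metadata()
    assert meta["scaling"] == "unit_variance" and meta["linkage"] == "average"
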