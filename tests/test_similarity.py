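import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from oracles import energy_distance_loops
from perturbatlas.core import CountMatrix
from perturbatlas.similarity import (
    cluster_similarity,
    compute_effect_vectors,
    cosine_matrix,
    deg_jaccard,
    edistance_test,
    energy_distance,
    gate_perturbations,
    knn_impute_hierarchical,
    linkage_to_newick,
    normalize_for_similarity,
)


class TestEnergyDistance:
    def test_two_point_masses(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0]])
        Y = np.array([[3.0, 4.0], [3.0, 4.0]])
        assert energy_distance(X, Y) == pytest.approx(50.0)

    def test_identical_multisets(self):
        X = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        # V-statistic convention: exact identity; unbiased U-statistic:
        # slightly negative on the literally identical multiset
        assert energy_distance(X, X.copy(), unbiased=False) == \
            pytest.approx(0.0)
        assert energy_distance(X, X.copy()) <= 0.0

    def test_singleton_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            energy_distance(np.zeros((1, 2)), np.zeros((3, 2)))

    @pytest.mark.parametrize("metric,squared", [
        ("sqeuclidean", True), ("euclidean", False)])
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_double_loop_oracle(self, metric, squared, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(rng.integers(2, 30), 5))
        Y = rng.normal(size=(rng.integers(2, 30), 5))
        assert energy_distance(X, Y, metric=metric) == pytest.approx(
            energy_distance_loops(X, Y, squared=squared), abs=1e-10)

    def test_translation_and_permutation_invariance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 4))
        Y = rng.normal(size=(25, 4)) + 1.0
        e = energy_distance(X, Y)
        shift = rng.normal(size=4)
        assert energy_distance(X + shift, Y + shift) == pytest.approx(e)
        perm = rng.permutation(len(X))
        assert energy_distance(X[perm], Y) == pytest.approx(e)


class TestEdistanceTest:
    def test_separated_groups_hit_permutation_floor(self):
        rng = np.random.default_rng(12)
        groups = {
            "a": rng.normal(0, 1, size=(100, 5)),
            "b": rng.normal(2.0, 1, size=(100, 5)),
        }
        res = edistance_test(groups, n_permutations=99, seed=0)
        assert res.iloc[0]["p"] == pytest.approx(1 / 100)

    def test_zero_permutations_returns_distances_only(self):
        rng = np.random.default_rng(13)
        groups = {"a": rng.normal(size=(10, 3)), "b": rng.normal(size=(10, 3))}
        res = edistance_test(groups, n_permutations=0, seed=0)
        assert np.isnan(res.iloc[0]["p"])
        assert np.isfinite(res.iloc[0]["edistance"])

    def test_null_rejection_rate_near_alpha(self, null_metrics):
        rate = null_metrics["edistance_null_rejection_at_005"]
        n = null_metrics["n_edistance_pairs"]
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(rate - 0.05) <= 3 * se


class TestGate:
    def _results(self, n, lfc, q=0.01):
        return pd.DataFrame({
            "perturbation": ["p"] * n, "group": ["CT0"] * n,
            "gene": [f"g{i}" for i in range(n)],
            "lfc": [lfc] * n, "q": [q] * n,
        })

    def test_five_strong_degs_pass(self):
        out = gate_perturbations(self._results(5, 0.6))
        assert len(out) == 1

    def test_lfc_exactly_at_half_is_excluded(self):
        out = gate_perturbations(self._results(5, 0.5))
        assert len(out) == 0

    def test_no_degs_excluded(self):
        out = gate_perturbations(self._results(5, 0.6, q=0.5))
        assert len(out) == 0


class TestEffectVectors:
    def _embedding_and_cells(self):
        emb = pd.DataFrame(
            [[0.0, 0.0], [2.0, 0.0], [4.0, 4.0], [6.0, 4.0], [1.0, 1.0]],
            index=["n1", "n2", "a1", "a2", "b1"],
        )
        cells = pd.DataFrame({
            "cell_id": ["n1", "n2", "a1", "a2", "b1"],
            "guide_class": ["non_targeting"] * 2 + ["targeting"] * 3,
            "perturbation": [None, None, "geneA", "geneA", "geneB"],
            "group": ["CT0"] * 5,
        })
        return emb, cells

    def test_vector_is_mean_minus_control_mean(self):
        emb, cells = self._embedding_and_cells()
        vec = compute_effect_vectors(emb, cells)
        np.testing.assert_allclose(
            vec.loc[("geneA", "CT0")].to_numpy()[:2], [4.0, 4.0])
        assert vec.loc[("geneA", "CT0"), "n_cells"] == 2

    def test_missing_controls_rejected(self):
        emb, cells = self._embedding_and_cells()
        cells["guide_class"] = "targeting"
        with pytest.raises(ValueError, match="control"):
            compute_effect_vectors(emb, cells)

    def test_cosine_of_colinear_and_orthogonal(self):
        vec = pd.DataFrame([[1.0, 1.0, 0.0], [2.0, 2.0, 0.0], [0.0, 0.0, 3.0]],
                           index=["a", "b", "c"])
        sim = cosine_matrix(vec)
        assert sim.loc["a", "b"] == pytest.approx(1.0)
        assert sim.loc["a", "c"] == pytest.approx(0.0)

    def test_zero_vector_similarity_flagged_as_zero(self):
        vec = pd.DataFrame([[0.0, 0.0], [1.0, 1.0]], index=["z", "a"])
        sim = cosine_matrix(vec)
        assert sim.loc["z", "a"] == 0.0


class TestClustering:
    def test_shared_program_vectors_merge_first(self):
        rng = np.random.default_rng(14)
        base = rng.normal(size=10)
        v1 = base + rng.normal(0, 0.1, 10)
        v2 = base + rng.normal(0, 0.1, 10)
        v3 = rng.normal(size=10)
        vec = pd.DataFrame([v1, v2, v3], index=["p1", "p2", "p3"])
        sim = cosine_matrix(vec)
        assert sim.loc["p1", "p2"] > max(sim.loc["p1", "p3"],
                                         sim.loc["p2", "p3"])
        Z, order = cluster_similarity(sim)
        # first merge joins the two shared-program perturbations
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_newick_output_parses(self):
        import io

        import skbio

        vec = pd.DataFrame(np.eye(4) + 0.1, index=list("abcd"))
        sim = cosine_matrix(vec)
        Z, _ = cluster_similarity(sim)
        nwk = linkage_to_newick(Z, list(sim.index))
        tree = skbio.TreeNode.read(io.StringIO(nwk))
        assert {t.name for t in tree.tips()} == set("abcd")

    def test_planted_modules_recovered(self, recovery_metrics):
        assert recovery_metrics["module_ari"] >= 0.9


class TestJaccard:
    @pytest.mark.parametrize("a,b,expected", [
        ({"a", "b", "c"}, {"b", "c", "d"}, 0.5),
        ({"a"}, {"a"}, 1.0),
        ({"a"}, {"b"}, 0.0),
        (set(), set(), 0.0),
    ])
    def test_values(self, a, b, expected):
        assert deg_jaccard(a, b) == pytest.approx(expected)


class TestNormalization:
    def test_low_rank_data_concentrates_variance(self):
        rng = np.random.default_rng(15)
        # counts driven by a 2-factor latent structure
        u = rng.gamma(2.0, 1.0, size=(200, 2))
        v = rng.gamma(2.0, 1.0, size=(2, 120))
        X = rng.poisson(u @ v * 3)
        cm = CountMatrix([f"c{i}" for i in range(200)],
                         [f"g{i}" for i in range(120)], sp.csr_matrix(X))
        emb = normalize_for_similarity(cm, n_hvg=100, n_pcs=20)
        var = emb.var(axis=0).to_numpy()
        assert var[:2].sum() / var.sum() > 0.5

    def test_duplicated_cells_get_identical_rows(self):
        rng = np.random.default_rng(16)
        X = rng.poisson(2.0, size=(60, 80)) + 1
        X[1] = X[0]
        cm = CountMatrix([f"c{i}" for i in range(60)],
                         [f"g{i}" for i in range(80)], sp.csr_matrix(X))
        emb = normalize_for_similarity(cm, n_hvg=50, n_pcs=10)
        np.testing.assert_allclose(emb.iloc[0], emb.iloc[1], atol=1e-8)

    def test_too_few_cells_rejected(self):
        cm = CountMatrix(["c1", "c2"], ["g1", "g2"],
                         sp.csr_matrix(np.ones((2, 2))))
        with pytest.raises(ValueError, match="at least"):
            normalize_for_similarity(cm, n_pcs=50)


class TestKnnImputation:
    def test_singleton_group_unchanged(self):
        expr = pd.DataFrame([[1.0, 2.0], [5.0, 6.0]], index=["a", "b"])
        hier = pd.DataFrame({"lvl": ["x", "y"]}, index=["a", "b"])
        out = knn_impute_hierarchical(expr, hier, k=15)
        pd.testing.assert_frame_equal(out, expr)

    def test_identical_cells_are_fixed_point(self):
        expr = pd.DataFrame(np.ones((10, 4)),
                            index=[f"c{i}" for i in range(10)])
        hier = pd.DataFrame({"lvl": ["g"] * 10}, index=expr.index)
        out = knn_impute_hierarchical(expr, hier, k=3)
        np.testing.assert_allclose(out.to_numpy(), 1.0)

    def test_smoothing_shrinks_within_group_variance(self):
        rng = np.random.default_rng(17)
        a = rng.normal(0, 1, size=(50, 6)) + 5
        b = rng.normal(0, 1, size=(50, 6)) - 5
        expr = pd.DataFrame(np.vstack([a, b]),
                            index=[f"c{i}" for i in range(100)])
        hier = pd.DataFrame({"lvl": ["A"] * 50 + ["B"] * 50}, index=expr.index)
        out = knn_impute_hierarchical(expr, hier, k=15)
        assert out.iloc[:50].var().sum() < expr.iloc[:50].var().sum()
        np.testing.assert_allclose(out.iloc[:50].mean(), expr.iloc[:50].mean(),
                                   atol=0.5)
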