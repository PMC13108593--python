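import numpy as np
import pandas as pd
import pytest

from oracles import fisher_p_enumeration
from perturbatlas.enrichment import (
    burden_log10,
    compare_groups,
    deg_burden,
    expression_matched_bootstrap,
    gene_set_enrichment,
    inheritance_scores,
    loeuf_strata,
    module_convergence,
    stratify_by_evidence,
)


def de_frame(counts_by_pert):
    """Build a minimal DE result frame with the given DEG counts per
    perturbation spread over two groups (cell types)."""
    rows = []
    for pert, (n_ct0, n_ct1) in counts_by_pert.items():
        i = 0
        for grp, n in (("CT0", n_ct0), ("CT1", n_ct1)):
            for _ in range(n):
                rows.append((pert, grp, f"deg{i}", 1.0, 0.01))
                i += 1
            rows.append((pert, grp, "null_gene", 0.0, 0.9))
    return pd.DataFrame(rows, columns=["perturbation", "group", "gene",
                                       "lfc", "q"])


class TestBurden:
    def test_totals_and_log_transform(self):
        mat = deg_burden(de_frame({"p1": (10, 90)}), min_total=None)
        assert mat.loc["p1"].sum() == 100
        assert burden_log10(mat).loc["p1"].sum() == pytest.approx(
            np.log10(11) + np.log10(91))

    def test_row_minmax_scaling(self):
        mat = deg_burden(de_frame({"p1": (10, 90)}), min_total=None,
                         scale_rows=True)
        assert sorted(mat.loc["p1"].tolist()) == [0.0, 1.0]

    def test_low_total_rows_excluded(self):
        mat = deg_burden(de_frame({"small": (4, 5), "big": (30, 5)}),
                         min_total=10)
        assert list(mat.index) == ["big"]

    def test_category_aggregation(self):
        mat = deg_burden(de_frame({"p1": (5, 5), "p2": (10, 0)}),
                         categories={"cat": {"p1", "p2"}}, min_total=None)
        assert mat.loc["cat"].sum() == 20


class TestCompareGroups:
    def test_two_group_exact_p(self):
        totals = pd.Series([100, 200, 300, 1, 2, 3])
        grouping = pd.Series(["A"] * 3 + ["B"] * 3)
        res = compare_groups(totals, grouping)
        assert res.iloc[0]["p"] == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        totals = pd.Series([5, 5, 5, 5])
        grouping = pd.Series(["A", "A", "B", "B"])
        assert compare_groups(totals, grouping).iloc[0]["p"] == 1.0

    def test_multi_group_runs_kruskal_then_pairwise(self):
        rng = np.random.default_rng(0)
        totals = pd.Series(rng.random(30))
        grouping = pd.Series(["lo"] * 10 + ["mid"] * 10 + ["hi"] * 10)
        res = compare_groups(totals, grouping, reference="mid")
        assert res.iloc[0]["test"] == "kruskal_wallis"
        assert set(res["test"][1:]) == {"wilcoxon_vs_reference"}
        assert len(res) == 3

    def test_degenerate_grouping_rejected(self):
        with pytest.raises(ValueError, match="groups"):
            compare_groups(pd.Series([1, 2]), pd.Series(["A", "A"]))


class TestStratification:
    def test_loeuf_deciles_map_to_strata(self):
        d = pd.Series([0, 2, 3, 5, 6, 9], index=list("abcdef"))
        s = loeuf_strata(d)
        assert s.tolist() == ["constrained", "constrained", "intermediate",
                              "intermediate", "tolerant", "tolerant"]

    def test_five_quantiles_over_ten_genes(self):
        v = pd.Series(range(10), index=[f"g{i}" for i in range(10)])
        s = stratify_by_evidence(v, mode="quantiles")
        assert s.value_counts().tolist() == [2] * 5

    def test_median_split_with_inclusion_threshold(self):
        v = pd.Series([25.0, 30.0, 15.0], index=["g1", "g2", "g3"])
        s = stratify_by_evidence(v, mode="median_split",
                                 inclusion_threshold=20)
        # g3 excluded (<= 20); split of {25, 30} at 27.5
        assert pd.isna(s["g3"])
        assert s["g1"] == "bottom" and s["g2"] == "top"

    def test_all_tied_values_single_stratum(self):
        v = pd.Series([1.0, 1.0, 1.0])
        assert set(stratify_by_evidence(v)) == {"all_tied"}


class TestInheritanceScores:
    def test_weights_sum_per_mode(self):
        ev = pd.DataFrame({
            "gene": ["g1", "g1", "g1", "g2"],
            "evidence_type": ["exome_wide_significant", "fdr_significant",
                              "curated_strong", "curated_limited"],
            "inheritance_mode": ["dominant", "dominant", "recessive",
                                 "x_linked"],
        })
        s = inheritance_scores(ev)
        assert s.loc["g1", "dominant_score"] == 15.0
        assert s.loc["g1", "recessive_score"] == 7.5
        assert s.loc["g2", "x_linked_score"] == 2.5
        assert s.loc["g2", "dominant_score"] == 0.0

    def test_loeuf_weight_is_proportional_to_constraint(self):
        ev = pd.DataFrame({
            "gene": ["g1", "g2"],
            "evidence_type": ["loeuf", "loeuf"],
            "loeuf_decile": [0, 5],
            "inheritance_mode": ["dominant", "dominant"],
        })
        s = inheritance_scores(ev)
        assert s.loc["g1", "dominant_score"] == 10.0
        assert s.loc["g2", "dominant_score"] == 5.0

    def test_unknown_evidence_type_rejected(self):
        ev = pd.DataFrame({"gene": ["g"], "evidence_type": ["rumor"],
                           "inheritance_mode": ["dominant"]})
        with pytest.raises(ValueError, match="evidence type"):
            inheritance_scores(ev)


class TestGeneSetEnrichment:
    def _fixture(self):
        universe = {f"g{i}" for i in range(1000)}
        gene_set = {f"g{i}" for i in range(100)}
        degs = {f"g{i}" for i in range(10)} | {f"g{i}" for i in range(500, 540)}
        return universe, gene_set, degs

    def test_fold_enrichment_arithmetic(self):
        universe, gene_set, degs = self._fixture()
        res = gene_set_enrichment({"q": degs}, {"set": gene_set}, universe,
                                  exclude_self=False)
        row = res.iloc[0]
        assert row["expected"] == pytest.approx(5.0)
        assert row["overlap"] == 10
        assert row["fold_enrichment"] == pytest.approx(2.0)

    def test_p_matches_enumeration(self):
        universe = {f"g{i}" for i in range(150)}
        gene_set = {f"g{i}" for i in range(30)}
        degs = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(100, 120)}
        res = gene_set_enrichment({"q": degs}, {"set": gene_set}, universe,
                                  exclude_self=False)
        a = len(degs & gene_set)
        b = len(degs) - a
        c = len(gene_set) - a
        d = len(universe) - a - b - c
        assert res.iloc[0]["p"] == pytest.approx(
            fisher_p_enumeration(a, b, c, d, "greater"), abs=1e-10)

    def test_small_deg_sets_skipped(self):
        universe, gene_set, _ = self._fixture()
        res = gene_set_enrichment({"q": {f"g{i}" for i in range(19)}},
                                  {"set": gene_set}, universe)
        assert res.iloc[0]["skipped"]
        assert res.iloc[0]["reason"] == "min_degs"

    def test_self_gene_excluded_from_own_degs(self):
        universe, gene_set, degs = self._fixture()
        res = gene_set_enrichment({"g0": degs | {"g0"}}, {"set": gene_set},
                                  universe, exclude_self=True)
        assert res.iloc[0]["n_degs"] == len((degs | {"g0"}) - {"g0"})

    def test_overlap_equal_expected_gives_fe_one(self):
        universe = {f"g{i}" for i in range(100)}
        gene_set = {f"g{i}" for i in range(50)}
        degs = {f"g{i}" for i in range(30, 70)}  # 40 degs, overlap 20 = expected
        res = gene_set_enrichment({"q": degs}, {"set": gene_set}, universe,
                                  exclude_self=False)
        assert res.iloc[0]["fold_enrichment"] == pytest.approx(1.0)


class TestExpressionMatchedBootstrap:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(400)]
        expression = pd.Series(rng.lognormal(0, 1, 400), index=genes)
        target = set(genes[:40])
        pool = set(genes) - target
        return genes, expression, target, pool

    def test_matched_sets_preserve_bin_counts(self):
        genes, expression, target, pool = self._setup()
        universe = set(genes)
        boot = expression_matched_bootstrap(
            target, pool, expression, {"q": set(genes[200:260])}, universe,
            n_boot=20, seed=1)
        assert sum(boot.bin_counts.values()) == len(target)

    def test_matched_sets_never_include_target(self):
        genes, expression, target, pool = self._setup()
        rng = np.random.default_rng(3)
        # re-draw with the same binning logic and check exclusion directly:
        # any overlap of a matched set with the target would inflate FE of
        # a query equal to the target set itself beyond its null
        boot = expression_matched_bootstrap(
            target, pool, expression, {"self": target}, set(genes),
            n_boot=50, seed=2)
        assert max(boot.fe_distribution["self"]) == 0.0

    def test_expression_independent_query_centers_near_one(self):
        genes, expression, target, pool = self._setup(seed=5)
        rng = np.random.default_rng(6)
        query = set(rng.choice(genes, 120, replace=False))
        boot = expression_matched_bootstrap(
            target, pool, expression, {"q": query}, set(genes),
            n_boot=400, seed=7)
        assert 0.8 <= boot.median_fe["q"] <= 1.25

    def test_underfilled_bin_rejected(self):
        genes = [f"g{i}" for i in range(30)]
        expression = pd.Series(np.arange(30, dtype=float), index=genes)
        target = set(genes[:25])  # pool of 5 cannot match 25 target genes
        with pytest.raises(ValueError, match="bin"):
            expression_matched_bootstrap(
                target, set(genes) - target, expression, {}, set(genes),
                n_boot=5, n_bins=2, seed=0)


class TestModuleConvergence:
    def test_percentages(self):
        clusters = {"cl1": {"a", "b", "c", "d"}}
        res = module_convergence(clusters, {"t1": {"a", "b"},
                                            "t2": {"x"},
                                            "t3": {"a", "b", "c", "d"}})
        assert res.loc["cl1", "t1"] == 50.0
        assert res.loc["cl1", "t2"] == 0.0
        assert res.loc["cl1", "t3"] == 100.0

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            module_convergence({"cl": set()}, {"t": {"a"}})


class TestBootstrapOnRecovery:
    def test_independent_queries_give_unit_fe(self, recovery_metrics):
        assert 0.8 <= recovery_metrics["bootstrap_median_fe"] <= 1.25
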