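"""Disease-gene analytics over differential-expression results.

Covers DEG burden matrices per gene category and cell type, nonparametric
group comparisons of DEG totals, evidence-based stratification (LOEUF
deciles, inheritance scores, significance quantiles), one-sided Fisher
gene-set enrichment with fold enrichment, an expression-quantile-matched
bootstrap null, and network-module convergence percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kruskal, mannwhitneyu

from .core import (
    GeneSetCollection,
    benjamini_hochberg,
    bonferroni,
    fisher_exact_2x2,
    hypergeom_sf,
)

__all__ = [
    "deg_burden",
    "compare_groups",
    "stratify_by_evidence",
    "inheritance_scores",
    "loeuf_strata",
    "gene_set_enrichment",
    "expression_matched_bootstrap",
    "module_convergence",
    "BootstrapNull",
]


def deg_burden(
    de_results: pd.DataFrame,
    categories: dict[str, set[str]] | None = None,
    fdr: float = 0.05,
    min_total: int | None = 10,
    scale_rows: bool = False,
) -> pd.DataFrame:
    """DEG-count matrix, rows = perturbations or gene categories, columns =
    cell groups.

    With ``categories`` given, counts are summed across perturbations whose
    target belongs to each category.  Rows with fewer than ``min_total``
    total DEGs are dropped when the exclusion rule is active (pass None to
    disable).  ``scale_rows`` applies per-row min-max scaling to [0, 1].
    Raw counts are always recoverable: the log10 display transform
    (log10(x + 1)) lives in :func:`burden_log10`.
    """
    degs = de_results[de_results["q"] < fdr]
    counts = (
        degs.groupby(["perturbation", "group"]).size().unstack(fill_value=0)
    )
    # perturbations tested but without DEGs at this threshold keep zero rows
    all_perts = de_results["perturbation"].unique()
    counts = counts.reindex(all_perts, fill_value=0).sort_index()
    if categories is not None:
        rows = {}
        known = set(counts.index)
        for name, members in categories.items():
            present = sorted(known & members)
            rows[name] = counts.loc[present].sum(axis=0)
        counts = pd.DataFrame(rows).T
    if min_total is not None:
        counts = counts[counts.sum(axis=1) >= min_total]
    if scale_rows:
        lo = counts.min(axis=1)
        span = counts.max(axis=1) - lo
        span = span.replace(0, 1)
        counts = counts.sub(lo, axis=0).div(span, axis=0)
    return counts


def burden_log10(counts: pd.DataFrame) -> pd.DataFrame:
    """log10(x + 1) display transform of a burden matrix."""
    return np.log10(counts + 1)


def compare_groups(
    totals: pd.Series, grouping: pd.Series, reference: str | None = None
) -> pd.DataFrame:
    """Rank-based comparison of per-perturbation DEG totals across groups.

    Two groups: two-sided Wilcoxon rank-sum.  More: Kruskal-Wallis first,
    then pairwise rank-sum of every other group against ``reference``
    (required in the multi-group case).  P-values are reported unadjusted
    with the pairing structure recorded.
    """
    levels = [g for g in pd.unique(grouping) if pd.notna(g)]
    by = {g: totals[grouping == g].to_numpy(dtype=float) for g in levels}
    if len(levels) < 2 or any(len(v) < 2 for v in by.values()):
        raise ValueError("need >= 2 groups with >= 2 members each")
    rows = []
    if len(levels) == 2:
        a, b = levels
        res = mannwhitneyu(by[a], by[b], alternative="two-sided", method="auto")
        rows.append({"test": "wilcoxon", "group_a": a, "group_b": b,
                     "statistic": float(res.statistic),
                     "p": float(res.pvalue)})
    else:
        kw = kruskal(*by.values())
        rows.append({"test": "kruskal_wallis", "group_a": "|".join(map(str, levels)),
                     "group_b": "", "statistic": float(kw.statistic),
                     "p": float(kw.pvalue)})
        if reference is None:
            raise ValueError("multi-group comparison needs a reference group")
        for g in levels:
            if g == reference:
                continue
            res = mannwhitneyu(by[g], by[reference],
                               alternative="two-sided", method="auto")
            rows.append({"test": "wilcoxon_vs_reference", "group_a": g,
                         "group_b": reference,
                         "statistic": float(res.statistic),
                         "p": float(res.pvalue)})
    return pd.DataFrame(rows)


# evidence-type weights for inheritance-mode consensus scores; LOEUF-based
# evidence is weighted 10 * (1 - decile/10) so the most constrained decile
# scores 10 and weights fall off proportionally
DEFAULT_EVIDENCE_WEIGHTS = {
    "exome_wide_significant": 10.0,
    "fdr_significant": 5.0,
    "curated_definitive": 10.0,
    "curated_strong": 7.5,
    "curated_moderate": 5.0,
    "curated_limited": 2.5,
}

INHERITANCE_MODES = ("dominant", "recessive", "x_linked")


def inheritance_scores(
    evidence: pd.DataFrame,
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Consensus dominant/recessive/X-linked scores per gene.

    ``evidence`` has one row per (gene, evidence item): columns ``gene``,
    ``evidence_type`` (a key of the weight table, or ``"loeuf"`` with a
    ``loeuf_decile`` column), and ``inheritance_mode``.  Each row
    contributes its weight to the gene's score for that mode; rows with an
    unknown evidence type raise.
    """
    weights = DEFAULT_EVIDENCE_WEIGHTS if weights is None else weights
    evidence = evidence.copy()

    def weight_of(row) -> float:
        if row.evidence_type == "loeuf":
            decile = int(row.loeuf_decile)
            if not 0 <= decile <= 9:
                raise ValueError(f"LOEUF decile {decile} outside 0-9")
            return 10.0 * (1.0 - decile / 10.0)
        try:
            return float(weights[row.evidence_type])
        except KeyError:
            raise ValueError(f"unknown evidence type {row.evidence_type!r}")

    bad = set(evidence["inheritance_mode"]) - set(INHERITANCE_MODES)
    if bad:
        raise ValueError(f"unknown inheritance modes {sorted(bad)}")
    evidence["weight"] = [weight_of(r) for r in evidence.itertuples()]
    out = (
        evidence.pivot_table(index="gene", columns="inheritance_mode",
                             values="weight", aggfunc="sum", fill_value=0.0)
        .reindex(columns=list(INHERITANCE_MODES), fill_value=0.0)
    )
    out.columns = [f"{m}_score" for m in out.columns]
    return out


LOEUF_STRATA = {
    "constrained": range(0, 3),
    "intermediate": range(3, 6),
    "tolerant": range(6, 10),
}


def loeuf_strata(deciles: pd.Series) -> pd.Series:
    """Map LOEUF deciles 0-9 to constrained (0-2) / intermediate (3-5) /
    tolerant (6-9)."""
    def lab(d):
        for name, rng in LOEUF_STRATA.items():
            if d in rng:
                return name
        raise ValueError(f"LOEUF decile {d!r} outside 0-9")

    return deciles.map(lab)


def stratify_by_evidence(
    values: pd.Series,
    mode: str = "quantiles",
    n_quantiles: int = 5,
    inclusion_threshold: float | None = None,
) -> pd.Series:
    """Stratify genes by an evidence value.

    ``quantiles``: five (by default) quantile bins of the value
    distribution, labelled Q1 (lowest) .. Qn.  ``median_split``: genes above
    ``inclusion_threshold`` are kept and split into bottom/top halves at
    the median of the included scores (used for dominant > 20 and
    recessive > 10 inheritance scores).  All-tied values collapse to a
    single flagged stratum.
    """
    if values.nunique() == 1:
        return pd.Series("all_tied", index=values.index)
    if mode == "quantiles":
        return pd.Series(
            pd.qcut(values.rank(method="first"), n_quantiles,
                    labels=[f"Q{i + 1}" for i in range(n_quantiles)]).astype(str),
            index=values.index,
        )
    if mode == "median_split":
        if inclusion_threshold is None:
            raise ValueError("median_split needs an inclusion threshold")
        included = values[values > inclusion_threshold]
        med = included.median()
        out = pd.Series(np.nan, index=values.index, dtype=object)
        out[included.index] = np.where(included > med, "top", "bottom")
        return out
    raise ValueError(f"unknown stratification mode {mode!r}")


def gene_set_enrichment(
    deg_sets: dict[str, set[str]],
    gene_sets: GeneSetCollection | dict[str, set[str]],
    universe: set[str],
    min_degs: int = 20,
    correction: str = "bh",
    exclude_self: bool = True,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of each DEG set against each gene set.

    FE = observed overlap / expected overlap, expected = |DEG| * |set ∩
    universe| / |universe|.  ``deg_sets`` maps a query name (typically a
    perturbation target) to its DEG symbols; the target itself is removed
    from its own DEG list when ``exclude_self``.  Queries with fewer than
    ``min_degs`` unique DEGs are recorded as skipped.  Correction is BH
    (across all records) or Bonferroni.
    """
    sets = gene_sets.sets if isinstance(gene_sets, GeneSetCollection) else gene_sets
    N = len(universe)
    rows = []
    for query, degs in deg_sets.items():
        degs = set(degs) & universe
        if exclude_self:
            degs -= {query}
        if len(degs) < min_degs:
            rows.append({"query": query, "gene_set": "", "skipped": True,
                         "reason": "min_degs", "n_degs": len(degs),
                         "overlap": np.nan, "expected": np.nan,
                         "fold_enrichment": np.nan, "odds_ratio": np.nan,
                         "p": np.nan})
            continue
        for name, members in sets.items():
            m = set(members) & universe
            overlap = len(degs & m)
            expected = len(degs) * len(m) / N
            p = hypergeom_sf(overlap, N, len(m), len(degs))
            a = overlap
            b = len(degs) - overlap
            c = len(m) - overlap
            d = N - len(degs) - len(m) + overlap
            or_, _ = fisher_exact_2x2(a, b, c, d, alternative="greater")
            rows.append({
                "query": query, "gene_set": name, "skipped": False,
                "reason": "", "n_degs": len(degs), "overlap": overlap,
                "expected": expected,
                "fold_enrichment": overlap / expected if expected > 0 else np.nan,
                "odds_ratio": or_, "p": p,
            })
    out = pd.DataFrame(rows)
    tested = out.index[~out["skipped"]]
    adj = np.full(len(out), np.nan)
    if len(tested):
        p = out.loc[tested, "p"].to_numpy()
        adj[tested] = bonferroni(p) if correction == "bonferroni" else \
            benjamini_hochberg(p)
    out["p_adj"] = adj
    out["correction"] = correction
    return out


@dataclass
class BootstrapNull:
    """Expression-matched bootstrap null for fold enrichment."""

    fe_distribution: dict[str, np.ndarray]   # query -> bootstrap FE values
    median_fe: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    bin_counts: dict[int, int]               # target-set genes per bin

    def exceeds_background(self, query: str, observed_fe: float) -> bool:
        return observed_fe > self.ci_high[query]


def expression_matched_bootstrap(
    target_set: set[str],
    pool: set[str],
    expression: pd.Series,
    deg_sets: dict[str, set[str]],
    universe: set[str],
    n_boot: int = 1000,
    n_bins: int = 10,
    seed: int = 0,
) -> BootstrapNull:
    """Bootstrap FE of each query DEG set against expression-matched decoys.

    Pool ∪ target genes are binned into ``n_bins`` expression quantiles;
    each bootstrap set draws, per bin without replacement, exactly as many
    non-target pool genes as the target set has in that bin.  FE of every
    query is recomputed against each matched set, yielding a median and
    95% empirical confidence interval per query.
    """
    target_set = set(target_set)
    pool = set(pool) - target_set
    genes = sorted(target_set | pool)
    missing = [g for g in genes if g not in expression.index]
    if missing:
        raise ValueError(f"no expression value for {missing[:5]}")
    expr = expression.loc[genes]
    bins = pd.qcut(expr.rank(method="first"), n_bins, labels=False)
    target_bins = bins.loc[sorted(target_set)]
    bin_counts = target_bins.value_counts().to_dict()
    pool_by_bin = {
        b: np.array(sorted(set(idx) & pool))
        for b, idx in bins.groupby(bins).groups.items()
    }
    for b, need in bin_counts.items():
        have = len(pool_by_bin.get(b, ()))
        if have < need:
            raise ValueError(
                f"expression bin {b} has {have} pool genes, target needs {need}")
    rng = np.random.default_rng(seed)
    N = len(universe)
    queries = {q: set(d) & universe for q, d in deg_sets.items()}
    fe = {q: np.empty(n_boot) for q in queries}
    for i in range(n_boot):
        matched: list[str] = []
        for b, need in sorted(bin_counts.items()):
            take = rng.choice(pool_by_bin[b], size=need, replace=False)
            matched.extend(take.tolist())
        mset = set(matched) & universe
        for q, degs in queries.items():
            expected = len(degs) * len(mset) / N
            fe[q][i] = len(degs & mset) / expected if expected > 0 else np.nan
    return BootstrapNull(
        fe_distribution=fe,
        median_fe={q: float(np.median(v)) for q, v in fe.items()},
        ci_low={q: float(np.percentile(v, 2.5)) for q, v in fe.items()},
        ci_high={q: float(np.percentile(v, 97.5)) for q, v in fe.items()},
        bin_counts={int(k): int(v) for k, v in bin_counts.items()},
    )


def module_convergence(
    clusters: dict[str, set[str]], deg_sets: dict[str, set[str]]
) -> pd.DataFrame:
    """Percent of each network cluster's genes present in each target's DEG
    list: 100 * |cluster ∩ DEGs| / |cluster|."""
    rows = {}
    for cname, members in clusters.items():
        if not members:
            raise ValueError(f"cluster {cname!r} is empty")
        rows[cname] = {
            t: 100.0 * len(members & set(d)) / len(members)
            for t, d in deg_sets.items()
        }
    return pd.DataFrame(rows).T
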