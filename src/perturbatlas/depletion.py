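"""Library-normalized relative fitness test.

A perturbation that kills or handicaps cells of a given type is recovered
below its AAV library expectation in that type.  Per guide and cell type we
build the 2x2 table

    A = round(N_C * f_P)    expected perturbation cells (library fraction)
    B =                     observed perturbation cells
    C = round(N_C * f_NTC)  expected non-targeting cells (summed fraction)
    D =                     observed non-targeting cells

and run a two-sided Fisher exact test on [[A, B], [C, D]].  The odds ratio
is oriented as (A*D)/(B*C), so OR > 1 means the perturbation is recovered
below expectation relative to the non-targeting controls — a fitness
defect.  Gene-level calls require at least ``min_guides`` of a gene's
guides to individually pass the FDR and odds-ratio criteria, guarding
against single-guide off-target artefacts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import NON_TARGETING, TARGETING, benjamini_hochberg, fisher_exact_2x2

__all__ = [
    "build_contingency",
    "fitness_test",
    "depletion_guide_table",
    "call_depleted_genes",
    "run_depletion",
]


def build_contingency(
    cell_guides: pd.DataFrame,
    library: pd.DataFrame,
    group_label: str,
) -> pd.DataFrame:
    """Per-guide contingency rows for one cell group.

    ``cell_guides`` holds single-guide cells of the group: columns
    cell_barcode, guide_id.  Expected counts are rounded to the nearest
    integer for the exact test; unrounded expectations back the effect
    size.  Returns columns guide_id, target_gene, a, b, c, d,
    expected_unrounded, cell_type.
    """
    lib = library.set_index("guide_id")
    unknown = set(cell_guides["guide_id"]) - set(lib.index)
    if unknown:
        raise ValueError(f"guides absent from library: {sorted(unknown)[:5]}")
    n_c = len(cell_guides)
    observed = cell_guides.groupby("guide_id").size()
    nt_guides = lib.index[lib["guide_class"] == NON_TARGETING]
    f_ntc = lib.loc[nt_guides, "library_fraction"].sum()
    d = int(observed.reindex(nt_guides).fillna(0).sum())
    c = int(round(n_c * f_ntc))
    rows = []
    for guide_id, row in lib[lib["guide_class"] == TARGETING].iterrows():
        f_p = row["library_fraction"]
        if f_p <= 0:
            raise ValueError(f"guide {guide_id} has non-positive library fraction")
        a_exact = n_c * f_p
        rows.append({
            "guide_id": guide_id,
            "target_gene": row["target_gene"],
            "cell_type": group_label,
            "a": int(round(a_exact)),
            "b": int(observed.get(guide_id, 0)),
            "c": c,
            "d": d,
            "expected_unrounded": a_exact,
        })
    return pd.DataFrame(rows)


def fitness_test(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher test; OR = (A*D)/(B*C) so OR > 1 flags depletion.

    Degenerate all-zero margins report OR 1 and p 1.
    """
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0, 1.0
    return fisher_exact_2x2(a, b, c, d, alternative="two-sided")


def depletion_guide_table(contingency: pd.DataFrame) -> pd.DataFrame:
    """Run the fitness test per guide row and attach effect sizes.

    Effect size is log2(observed cell fraction / library fraction) using
    unrounded expectations; BH correction is applied by the caller across
    all (guide, cell_type) rows jointly.
    """
    out = contingency.copy()
    or_p = [fitness_test(r.a, r.b, r.c, r.d) for r in out.itertuples()]
    out["odds_ratio"] = [x[0] for x in or_p]
    out["p"] = [x[1] for x in or_p]
    with np.errstate(divide="ignore"):
        out["log2_fc_fraction"] = np.log2(
            out["b"].to_numpy() / out["expected_unrounded"].to_numpy())
    return out


def call_depleted_genes(
    guide_results: pd.DataFrame,
    fdr: float = 0.05,
    or_threshold: float = 1.2,
    min_guides: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """BH across all (guide, cell_type) pairs, then gene-level consistency.

    A (gene, cell_type) pair is flagged when at least ``min_guides`` guides
    individually satisfy q < fdr and OR > or_threshold.  Returns the
    augmented per-guide table and the per-gene call table.
    """
    guide_results = guide_results.copy()
    guide_results["q"] = benjamini_hochberg(guide_results["p"].to_numpy())
    guide_results["significant"] = (
        (guide_results["q"] < fdr) & (guide_results["odds_ratio"] > or_threshold)
    )
    gene = (
        guide_results.groupby(["target_gene", "cell_type"], sort=True)
        .agg(
            n_guides=("guide_id", "size"),
            n_significant_guides=("significant", "sum"),
            mean_log2_fc_fraction=("log2_fc_fraction", "mean"),
            median_odds_ratio=("odds_ratio", "median"),
        )
        .reset_index()
    )
    gene["gene_call"] = gene["n_significant_guides"] >= min_guides
    return guide_results, gene


def run_depletion(
    assignment_table: pd.DataFrame,
    annotations: pd.DataFrame,
    library: pd.DataFrame,
    groupby: str = "cell_type",
    fdr: float = 0.05,
    or_threshold: float = 1.2,
    min_guides: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fitness test across every cell group at the chosen resolution.

    Uses single-guide cells only, mirroring the assignment policy for
    unambiguous genotype-phenotype links.
    """
    singles = assignment_table[
        assignment_table["assignment_class"] == "single"
    ][["cell_barcode", "guides"]].rename(columns={"guides": "guide_id"})
    merged = singles.merge(
        annotations[["cell_id", groupby]],
        left_on="cell_barcode", right_on="cell_id", how="inner",
    )
    pieces = []
    for label, grp in merged.groupby(groupby, sort=True):
        pieces.append(build_contingency(grp, library, str(label)))
    contingency = pd.concat(pieces, ignore_index=True)
    per_guide = depletion_guide_table(contingency)
    return call_depleted_genes(per_guide, fdr, or_threshold, min_guides)
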