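"""Wilcoxon differential expression against a pooled non-targeting control,
with empirical FDR calibration from safe-targeting pseudo-genes.

Only cells with a single, unambiguously assigned guide enter the analysis.
Cells from all 400 non-targeting guides form one control pool per cell
group; every perturbation — gene targets and safe-targeting pseudo-genes
alike — is compared against that pool with a two-sided Wilcoxon rank-sum
test per gene on CP10K log1p normalized expression.  Safe-targeting guides
are randomly partitioned into pseudo-genes of four guides; because they cut
inert loci, any "discoveries" they yield estimate the false-discovery rate
of the targeting results at the same threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

from .core import (
    CountMatrix,
    NON_TARGETING,
    SAFE_TARGETING,
    benjamini_hochberg,
)

__all__ = [
    "normalize_cp10k_log1p",
    "pool_controls",
    "single_guide_cells",
    "wilcoxon_de",
    "build_pseudo_genes",
    "run_de",
    "calibrate_fdr",
]

LFC_EPS = 1e-9


def normalize_cp10k_log1p(X: sp.spmatrix | np.ndarray) -> np.ndarray:
    """Counts-per-10K per cell followed by log(1 + x); returns dense."""
    X = np.asarray(X.todense() if sp.issparse(X) else X, dtype=np.float64)
    depth = X.sum(axis=1, keepdims=True)
    depth[depth == 0] = 1.0
    return np.log1p(X / depth * 1e4)


def single_guide_cells(
    assignment_table: pd.DataFrame,
    annotations: pd.DataFrame,
    library: pd.DataFrame,
    qc: pd.DataFrame | None = None,
    groupby: str = "cell_type",
) -> pd.DataFrame:
    """QC-passing single-guide cells with their guide, class and group.

    Returns columns: cell_id, guide_id, guide_class, target_gene, group.
    """
    singles = assignment_table[
        assignment_table["assignment_class"] == "single"
    ][["cell_barcode", "guides"]].rename(
        columns={"cell_barcode": "cell_id", "guides": "guide_id"})
    out = singles.merge(
        library[["guide_id", "guide_class", "target_gene"]], on="guide_id")
    out = out.merge(
        annotations[["cell_id", groupby]].rename(columns={groupby: "group"}),
        on="cell_id",
    )
    if qc is not None:
        passing = set(qc.loc[qc["qc_pass"], "cell_id"])
        out = out[out["cell_id"].isin(passing)]
    return out.reset_index(drop=True)


def pool_controls(cells: pd.DataFrame) -> pd.DataFrame:
    """The unified control pool: single-guide non-targeting cells."""
    return cells[cells["guide_class"] == NON_TARGETING]


def build_pseudo_genes(
    library: pd.DataFrame, n: int = 100, size: int = 4, seed: int = 0
) -> dict[str, list[str]]:
    """Random disjoint partition of the safe-targeting guides into ``n``
    pseudo-genes of ``size`` guides each."""
    st = sorted(library.loc[
        library["guide_class"] == SAFE_TARGETING, "guide_id"])
    if len(st) != n * size:
        raise ValueError(
            f"need exactly {n * size} safe-targeting guides, found {len(st)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(st)
    return {
        f"pseudo_{i + 1:03d}": sorted(perm[i * size:(i + 1) * size])
        for i in range(n)
    }


def wilcoxon_de(
    pert: np.ndarray,
    ctrl: np.ndarray,
    gene_ids: list[str],
) -> pd.DataFrame:
    """Two-sided rank-sum test per gene (columns) between two normalized
    expression matrices; exact small-sample p where scipy supports it.

    Log2 fold change compares group means of the normalized values with a
    symmetric pseudo-count.  Columns that are constant across both groups
    are reported with p = 1 and lfc = 0.
    """
    res = mannwhitneyu(pert, ctrl, axis=0, alternative="two-sided",
                       method="auto")
    p = np.atleast_1d(np.asarray(res.pvalue, dtype=float))
    mean_p = pert.mean(axis=0)
    mean_c = ctrl.mean(axis=0)
    lfc = np.log2((mean_p + LFC_EPS) / (mean_c + LFC_EPS))
    constant = np.ptp(np.concatenate([pert, ctrl]), axis=0) == 0
    p = np.where(constant | ~np.isfinite(p), 1.0, p)
    return pd.DataFrame({
        "gene": gene_ids,
        "lfc": lfc,
        "p": p,
        "q": benjamini_hochberg(p),
    })


def run_de(
    counts: CountMatrix,
    cells: pd.DataFrame,
    pseudo_genes: dict[str, list[str]] | None = None,
    min_cells: int = 20,
    min_expressing: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DE of every perturbation against the pooled NT control, per group.

    ``cells`` comes from :func:`single_guide_cells`.  Targeting cells are
    grouped by target gene; safe-targeting cells by pseudo-gene when a
    partition is supplied.  Within each cell group, genes must be expressed
    in at least ``min_expressing`` of the group's cells, and both the
    perturbation and the control pool must have at least ``min_cells``
    cells.  BH runs within each (perturbation, group) gene family.

    Returns (results, skipped): results has perturbation, perturbation_class,
    group, gene, lfc, p, q, n_pert_cells, n_ctrl_cells.
    """
    guide_to_pseudo: dict[str, str] = {}
    if pseudo_genes:
        for pid, gids in pseudo_genes.items():
            for g in gids:
                guide_to_pseudo[g] = pid

    def perturbation_of(row) -> str | None:
        if row.guide_class == "targeting":
            return row.target_gene
        if row.guide_class == SAFE_TARGETING:
            return guide_to_pseudo.get(row.guide_id)
        return None

    cells = cells.copy()
    cells["perturbation"] = [perturbation_of(r) for r in cells.itertuples()]
    cell_index = {c: i for i, c in enumerate(counts.cell_ids)}

    results: list[pd.DataFrame] = []
    skipped: list[dict] = []
    for group, gcells in cells.groupby("group", sort=True):
        idx = np.array([cell_index[c] for c in gcells["cell_id"]])
        sub = counts.counts[idx]
        expressing = np.asarray((sub > 0).sum(axis=0)).ravel()
        gene_mask = expressing >= min_expressing
        if not gene_mask.any():
            continue
        gene_ids = [g for g, m in zip(counts.gene_ids, gene_mask) if m]
        norm = normalize_cp10k_log1p(sub[:, gene_mask])
        local = {c: i for i, c in enumerate(gcells["cell_id"])}
        ctrl_ids = pool_controls(gcells)["cell_id"]
        ctrl = norm[[local[c] for c in ctrl_ids]]
        if len(ctrl) < min_cells:
            skipped.append({"perturbation": "<control>", "group": group,
                            "n_cells": len(ctrl), "reason": "control_too_small"})
            continue
        for pert_name, pcells in gcells.dropna(
                subset=["perturbation"]).groupby("perturbation", sort=True):
            pmat = norm[[local[c] for c in pcells["cell_id"]]]
            if len(pmat) < min_cells:
                skipped.append({"perturbation": pert_name, "group": group,
                                "n_cells": len(pmat), "reason": "min_cells"})
                continue
            de = wilcoxon_de(pmat, ctrl, gene_ids)
            de.insert(0, "perturbation", pert_name)
            de.insert(1, "perturbation_class",
                      "pseudo" if pert_name in (pseudo_genes or {}) else "target")
            de.insert(2, "group", group)
            de["n_pert_cells"] = len(pmat)
            de["n_ctrl_cells"] = len(ctrl)
            results.append(de)
    res = (
        pd.concat(results, ignore_index=True)
        if results
        else pd.DataFrame(columns=[
            "perturbation", "perturbation_class", "group", "gene", "lfc",
            "p", "q", "n_pert_cells", "n_ctrl_cells"])
    )
    return res, pd.DataFrame(skipped)


def calibrate_fdr(
    de_results: pd.DataFrame,
    thresholds: tuple[float, ...] = (0.01, 0.05, 0.1, 0.2),
) -> pd.DataFrame:
    """Empirical FDR: mean DEG count per pseudo-gene over mean DEG count per
    targeting perturbation, clipped to [0, 1], per q threshold.

    DEG counts are totals across tested groups per perturbation; every
    tested perturbation contributes (zero counts included).  When no
    targeting perturbation has any DEG at a threshold the estimate is
    undefined and reported as NaN.
    """
    rows = []
    for t in thresholds:
        deg = (
            de_results.assign(is_deg=de_results["q"] < t)
            .groupby(["perturbation", "perturbation_class"])["is_deg"]
            .sum()
            .reset_index()
        )
        pseudo = deg.loc[deg["perturbation_class"] == "pseudo", "is_deg"]
        target = deg.loc[deg["perturbation_class"] == "target", "is_deg"]
        mean_pseudo = float(pseudo.mean()) if len(pseudo) else np.nan
        mean_target = float(target.mean()) if len(target) else np.nan
        if mean_target and mean_target > 0:
            fdr = min(1.0, (mean_pseudo if len(pseudo) else 0.0) / mean_target)
        else:
            fdr = np.nan
        rows.append({
            "threshold": t,
            "mean_degs_pseudo": mean_pseudo,
            "mean_degs_target": mean_target,
            "empirical_fdr": fdr,
            "pseudo_deg_q25": float(pseudo.quantile(0.25)) if len(pseudo) else np.nan,
            "pseudo_deg_median": float(pseudo.median()) if len(pseudo) else np.nan,
            "pseudo_deg_q75": float(pseudo.quantile(0.75)) if len(pseudo) else np.nan,
        })
    return pd.DataFrame(rows)
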