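"""Cell-level quality control: minimum detected genes and the ambient score.

The ambient score asks whether a cell's expression profile is
distinguishable from a random draw out of the pooled ("ambient")
gene-frequency background.  For cell i with depth n_i and pooled gene
proportions p_g over G genes,

    MSE_i     = (1/G) * sum_g (x_ig - p_g * n_i)^2
    E[MSE_i]  = (1/G) * sum_g n_i * p_g * (1 - p_g)
    score_i   = ln MSE_i - ln E[MSE_i]

E[MSE_i] is the multinomial expectation of MSE_i, so empty-droplet-like
cells — ones whose contents look like a random sample of the background —
peak at score 0, while genuinely structured cells deviate upward.  Cells
scoring below the threshold are removed as ambient-indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CountMatrix

__all__ = ["AmbientModel", "compute_ambient_scores", "filter_cells"]


@dataclass
class AmbientModel:
    p_g: np.ndarray
    mse: np.ndarray
    expected_mse: np.ndarray
    ambient_score: np.ndarray
    n_genes: int


def compute_ambient_scores(counts: CountMatrix) -> AmbientModel:
    """Vectorised ambient model over a cells x genes count matrix.

    Every cell must have at least one UMI.  A cell with MSE exactly 0
    (profile identical to the scaled background) gets score −inf, the
    maximally ambient-like sentinel.
    """
    X = counts.counts
    n_i = counts.total_umis().astype(float)
    if (n_i == 0).any():
        raise ValueError("cells with zero UMIs must be filtered before QC")
    total = X.sum()
    p_g = np.asarray(X.sum(axis=0)).ravel() / total
    G = counts.n_genes
    # MSE_i = (1/G) [ sum_g x_ig^2 - 2 n_i sum_g x_ig p_g + n_i^2 sum_g p_g^2 ]
    sq = np.asarray(X.multiply(X).sum(axis=1)).ravel()
    cross = np.asarray(X @ p_g).ravel()
    mse = (sq - 2.0 * n_i * cross + n_i ** 2 * (p_g ** 2).sum()) / G
    mse = np.maximum(mse, 0.0)  # guard tiny negative rounding
    expected = n_i * (p_g * (1.0 - p_g)).sum() / G
    with np.errstate(divide="ignore"):
        score = np.log(mse) - np.log(expected)
    return AmbientModel(p_g, mse, expected, score, G)


def filter_cells(
    counts: CountMatrix,
    min_genes: int = 2000,
    ambient_threshold: float = 0.09,
    ambient: AmbientModel | None = None,
) -> pd.DataFrame:
    """QC report with pass/fail per cell.

    A cell passes when it has at least ``min_genes`` detected genes AND its
    ambient score is at or above ``ambient_threshold`` (cells below the
    threshold sit in the empty-droplet peak near 0 and are removed).  The
    background p_g is computed on the cells that survive the gene-count
    filter, before ambient filtering.
    """
    genes_detected = counts.genes_detected()
    pass_genes = genes_detected >= min_genes
    score = np.full(counts.n_cells, np.nan)
    if pass_genes.any():
        sub = counts.subset_cells(pass_genes)
        ambient = compute_ambient_scores(sub) if ambient is None else ambient
        score[np.flatnonzero(pass_genes)] = ambient.ambient_score
    pass_ambient = np.where(np.isnan(score), False, score >= ambient_threshold)
    reason = np.select(
        [~pass_genes, ~pass_ambient],
        ["min_genes", "ambient"],
        default="",
    )
    return pd.DataFrame({
        "cell_id": counts.cell_ids,
        "n_genes": genes_detected,
        "n_umis": counts.total_umis(),
        "ambient_score": score,
        "qc_pass": pass_genes & pass_ambient,
        "reason": reason,
    })
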