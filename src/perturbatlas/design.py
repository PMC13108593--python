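"""Screen-design scoring rubric.

Candidate genes are ranked by S = 10*w_c + 2*(w_a + w_b) + 0.2*E_p, where
w_c is the primary disease-association weight, w_a and w_b are secondary
functional/ontological weights (binary membership indicators by default),
and E_p is the gene's whole-tissue expression decile (1..10).  Genes with
S at or above the cutoff (default 3.8) are selected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["expression_deciles", "score_targets"]


def expression_deciles(mean_expression: pd.Series) -> pd.Series:
    """Ascending expression deciles labelled 1..10, near-equal bin sizes,
    ties broken by stable input order.  All-equal inputs collapse into a
    single decile (label 1)."""
    if len(mean_expression) == 0:
        raise ValueError("empty expression input")
    if (mean_expression < 0).any():
        raise ValueError("mean expression must be non-negative")
    if mean_expression.nunique() == 1:
        return pd.Series(1, index=mean_expression.index, dtype=int)
    ranks = mean_expression.rank(method="first")
    dec = pd.qcut(ranks, 10, labels=False, duplicates="drop") + 1
    return dec.astype(int)


def score_targets(
    weights: pd.DataFrame, e_p: pd.Series, cutoff: float = 3.8
) -> pd.DataFrame:
    """Score and select targets.

    ``weights`` needs columns w_c, w_a, w_b in [0, 1] indexed by gene;
    ``e_p`` holds the expression decile for every scored gene.  Selection
    is inclusive at the cutoff.
    """
    for col in ("w_c", "w_a", "w_b"):
        w = weights[col]
        if ((w < 0) | (w > 1)).any():
            raise ValueError(f"{col} must lie in [0, 1]")
    missing = weights.index.difference(e_p.index)
    if len(missing):
        raise ValueError(f"missing expression decile for {list(missing)[:5]}")
    ep = e_p.loc[weights.index].astype(float)
    score = (10.0 * weights["w_c"]
             + 2.0 * (weights["w_a"] + weights["w_b"])
             + 0.2 * ep)
    return pd.DataFrame({
        "w_c": weights["w_c"], "w_a": weights["w_a"], "w_b": weights["w_b"],
        "expression_decile": ep.astype(int),
        "score": np.round(score, 12),
        "selected": score >= cutoff - 1e-12,
    })
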