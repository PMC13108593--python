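"""Perturbation-similarity layer.

Cells of a cell type are embedded by the standard single-cell recipe
(CP10K, log1p, top highly variable genes, per-gene z-scaling, PCA to 50
components).  In that space, perturbations are compared three ways:

* **Energy distance** between the point clouds of two perturbations, with a
  label-permutation test.  For point sets X, Y the statistic is
  ``2 E d(x, y) − E d(x, x') − E d(y, y')`` with self-pairs excluded from
  the within-group means; the default pairwise metric is squared Euclidean
  (the common single-cell e-distance convention), with plain Euclidean
  available.
* **Effect vectors**: mean embedding of a perturbation's cells minus the
  mean of control cells in the same context, compared by cosine similarity
  and organised by hierarchical clustering (Euclidean distance between
  similarity-matrix rows, average linkage).
* **DEG-set Jaccard similarity.**

A group-restricted iterative KNN imputation over a label hierarchy
(coarse to fine) is included for de-noised visualisation matrices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import cdist, pdist
from sklearn.neighbors import NearestNeighbors

from .core import CountMatrix, benjamini_hochberg

__all__ = [
    "normalize_for_similarity",
    "gate_perturbations",
    "energy_distance",
    "edistance_test",
    "compute_effect_vectors",
    "cosine_matrix",
    "cluster_similarity",
    "linkage_to_newick",
    "deg_jaccard",
    "knn_impute_hierarchical",
]


def normalize_for_similarity(
    counts: CountMatrix,
    cell_ids: list[str] | None = None,
    n_hvg: int = 2000,
    n_pcs: int = 50,
    random_state: int = 0,
) -> pd.DataFrame:
    """CP10K -> log1p -> top-``n_hvg`` HVGs -> z-scale -> PCA embedding.

    Returns a cells x components DataFrame indexed by cell ID.  Requires at
    least ``n_pcs + 1`` cells; when fewer genes than ``n_hvg`` are variable,
    all variable genes are used.
    """
    import warnings

    import anndata as ad
    import scanpy as sc

    if cell_ids is not None:
        keep = {c for c in cell_ids}
        mask = np.array([c in keep for c in counts.cell_ids])
        counts = counts.subset_cells(mask)
    if counts.n_cells < n_pcs + 1:
        raise ValueError(
            f"need at least {n_pcs + 1} cells for a {n_pcs}-component embedding")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adata = ad.AnnData(
            counts.counts.astype(np.float32),
            obs=pd.DataFrame(index=counts.cell_ids),
            var=pd.DataFrame(index=counts.gene_ids),
        )
        sc.pp.normalize_total(adata, target_sum=1e4)
        sc.pp.log1p(adata)
        # constant genes carry no dispersion signal and are never selected
        n_top = min(n_hvg, adata.n_vars)
        sc.pp.highly_variable_genes(adata, n_top_genes=n_top, flavor="seurat")
        adata = adata[:, adata.var["highly_variable"]].copy()
        sc.pp.scale(adata)
        n_comps = min(n_pcs, adata.n_obs - 1, adata.n_vars - 1)
        sc.pp.pca(adata, n_comps=n_comps, svd_solver="arpack",
                  random_state=random_state)
    return pd.DataFrame(np.asarray(adata.obsm["X_pca"], dtype=np.float64),
                        index=counts.cell_ids)


def gate_perturbations(
    de_results: pd.DataFrame,
    min_degs: int = 5,
    min_abs_lfc: float = 0.5,
    fdr: float = 0.05,
    per_group: bool = True,
) -> pd.DataFrame:
    """Perturbation(-context) pairs with at least ``min_degs`` DEGs at
    q < fdr and |LFC| strictly greater than ``min_abs_lfc``."""
    hits = de_results[
        (de_results["q"] < fdr) & (de_results["lfc"].abs() > min_abs_lfc)
    ]
    keys = ["perturbation", "group"] if per_group else ["perturbation"]
    n = hits.groupby(keys).size().rename("n_degs").reset_index()
    return n[n["n_degs"] >= min_degs].reset_index(drop=True)


def _pairwise(X: np.ndarray, Y: np.ndarray, metric: str) -> np.ndarray:
    if metric == "sqeuclidean":
        return cdist(X, Y, metric="sqeuclidean")
    if metric == "euclidean":
        return cdist(X, Y, metric="euclidean")
    raise ValueError(f"unknown metric {metric!r}")


def energy_distance(X: np.ndarray, Y: np.ndarray,
                    metric: str = "sqeuclidean",
                    unbiased: bool = True) -> float:
    """E = 2 mean d(x, y) − mean d(x, x') − mean d(y, y').

    With ``unbiased=True`` (default) self-pairs are excluded from the
    within-group means, making the statistic a U-statistic with expectation
    exactly 0 for two independent samples of one distribution (it can go
    slightly negative by sampling noise, and E(X, X) on the literally
    identical multiset is slightly negative).  With ``unbiased=False``
    the zero-distance self-pairs are kept (V-statistic convention), so
    E(X, X) = 0 exactly but the null expectation is positive.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if len(X) < 2 or len(Y) < 2:
        raise ValueError("energy distance needs at least 2 points per group")
    between = _pairwise(X, Y, metric).mean()
    if unbiased:
        within_x = pdist(X, metric=metric).mean()
        within_y = pdist(Y, metric=metric).mean()
    else:
        within_x = _pairwise(X, X, metric).mean()
        within_y = _pairwise(Y, Y, metric).mean()
    return float(2.0 * between - within_x - within_y)


def _edist_from_submatrix(D: np.ndarray, ix: np.ndarray, iy: np.ndarray) -> float:
    nx, ny = len(ix), len(iy)
    between = D[np.ix_(ix, iy)].mean()
    wx = D[np.ix_(ix, ix)].sum() / (nx * (nx - 1))
    wy = D[np.ix_(iy, iy)].sum() / (ny * (ny - 1))
    return 2.0 * between - wx - wy


def edistance_test(
    groups: dict[str, np.ndarray],
    n_permutations: int = 1000,
    seed: int = 0,
    metric: str = "sqeuclidean",
) -> pd.DataFrame:
    """Pairwise e-distance with a label-permutation test and BH q-values.

    P-values use the add-one correction p = (1 + #{E_perm >= E_obs}) /
    (1 + n_permutations).  With ``n_permutations = 0`` the distances are
    still returned and p/q are NaN.
    """
    labels = sorted(groups)
    rng = np.random.default_rng(seed)
    rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            X, Y = np.asarray(groups[la]), np.asarray(groups[lb])
            pooled = np.vstack([X, Y])
            D = _pairwise(pooled, pooled, metric)
            np.fill_diagonal(D, 0.0)
            ix = np.arange(len(X))
            iy = np.arange(len(X), len(X) + len(Y))
            obs = _edist_from_submatrix(D, ix, iy)
            if n_permutations > 0:
                count = 0
                n = len(pooled)
                for _ in range(n_permutations):
                    perm = rng.permutation(n)
                    if _edist_from_submatrix(
                            D, perm[:len(X)], perm[len(X):]) >= obs:
                        count += 1
                p = (1 + count) / (1 + n_permutations)
            else:
                p = np.nan
            rows.append({"group_a": la, "group_b": lb,
                         "edistance": obs, "p": p})
    out = pd.DataFrame(rows)
    if len(out) and n_permutations > 0:
        out["q"] = benjamini_hochberg(out["p"].to_numpy())
    else:
        out["q"] = np.nan
    return out


def compute_effect_vectors(
    embedding: pd.DataFrame,
    cells: pd.DataFrame,
    control_class: str = "non_targeting",
) -> pd.DataFrame:
    """Mean embedding of each (perturbation, context) minus the control mean
    in the same context.

    ``cells`` needs columns cell_id, perturbation (NaN for control-class
    cells), guide_class and group; rows are indexed (perturbation, group)
    and an ``n_cells`` column records the perturbed-group size.
    """
    rows = []
    index = []
    n_cells = []
    for group, gcells in cells.groupby("group", sort=True):
        ctrl_ids = gcells.loc[gcells["guide_class"] == control_class, "cell_id"]
        ctrl_ids = [c for c in ctrl_ids if c in embedding.index]
        if not ctrl_ids:
            raise ValueError(f"no control cells in context {group!r}")
        ctrl_mean = embedding.loc[ctrl_ids].mean(axis=0).to_numpy()
        for pert, pcells in gcells.dropna(
                subset=["perturbation"]).groupby("perturbation", sort=True):
            ids = [c for c in pcells["cell_id"] if c in embedding.index]
            if not ids:
                continue
            rows.append(embedding.loc[ids].mean(axis=0).to_numpy() - ctrl_mean)
            index.append((pert, group))
            n_cells.append(len(ids))
    out = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index,
                                              names=["perturbation", "group"]))
    out.insert(out.shape[1], "n_cells", n_cells)
    return out


def cosine_matrix(vectors: pd.DataFrame) -> pd.DataFrame:
    """Pairwise cosine similarity between effect vectors (rows).

    Zero vectors have undefined cosine; their similarities are recorded as
    0.  The ``n_cells`` bookkeeping column is ignored if present.
    """
    V = vectors.drop(columns=["n_cells"], errors="ignore").to_numpy(dtype=float)
    norms = np.linalg.norm(V, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    sim = (V / safe[:, None]) @ (V / safe[:, None]).T
    sim[norms == 0, :] = 0.0
    sim[:, norms == 0] = 0.0
    np.clip(sim, -1.0, 1.0, out=sim)
    idx = vectors.index
    return pd.DataFrame(sim, index=idx, columns=idx)


def cluster_similarity(
    similarity: pd.DataFrame, method: str = "average"
) -> tuple[np.ndarray, list]:
    """Agglomerative clustering of the similarity matrix's rows using
    Euclidean distances; returns (scipy linkage matrix, leaf order)."""
    D = pdist(similarity.to_numpy(dtype=float), metric="euclidean")
    Z = sch.linkage(D, method=method, optimal_ordering=False)
    order = [similarity.index[i] for i in sch.leaves_list(Z)]
    return Z, order


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string."""
    tree = sch.to_tree(Z)

    def walk(node) -> str:
        if node.is_leaf():
            return str(labels[node.id])
        left, right = walk(node.left), walk(node.right)
        ln = max(node.dist - node.left.dist, 0.0)
        rn = max(node.dist - node.right.dist, 0.0)
        return f"({left}:{ln:.6g},{right}:{rn:.6g})"

    return walk(tree) + ";"


def deg_jaccard(set_a: set[str], set_b: set[str]) -> float:
    """|A ∩ B| / |A ∪ B|; two empty sets give 0."""
    union = set_a | set_b
    if not union:
        return 0.0
    return len(set_a & set_b) / len(union)


def knn_impute_hierarchical(
    expr: pd.DataFrame,
    hierarchy: pd.DataFrame,
    k: int = 15,
    metric: str = "cosine",
) -> pd.DataFrame:
    """Iterative group-restricted KNN smoothing over a label hierarchy.

    ``hierarchy`` holds one column per level, coarse to fine, indexed like
    ``expr`` (cells).  At each level every cell's expression row is replaced
    by the mean of its k nearest neighbours among cells sharing its label
    (k capped at the group size, self included), computed on the previous
    level's output.
    """
    values = expr.to_numpy(dtype=float).copy()
    cells = expr.index
    for level in hierarchy.columns:
        labels = hierarchy.loc[cells, level]
        new_values = np.empty_like(values)
        for lab, idx in labels.groupby(labels).groups.items():
            pos = np.array([cells.get_loc(c) for c in idx])
            if len(pos) == 0:
                raise ValueError(f"empty group {lab!r} at level {level!r}")
            sub = values[pos]
            kk = min(k, len(pos))
            if len(pos) == 1:
                new_values[pos] = sub
                continue
            nn = NearestNeighbors(n_neighbors=kk, metric=metric)
            nn.fit(sub)
            _, neigh = nn.kneighbors(sub)
            new_values[pos] = sub[neigh].mean(axis=1)
        values = new_values
    return pd.DataFrame(values, index=expr.index, columns=expr.columns)
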