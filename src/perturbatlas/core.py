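"""Shared data model, on-disk formats, and statistical utilities.

The canonical on-disk representation of a screen is plain text: a
MatrixMarket count matrix with sidecar cell/gene ID files, tab-separated
tables for annotations, guide reads, libraries and results, and GMT files
for gene sets.  In memory, counts live in a :class:`CountMatrix` (CSR
sparse, cells x genes) and tables in pandas DataFrames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy.stats import fisher_exact as _scipy_fisher

__all__ = [
    "CountMatrix",
    "GeneSetCollection",
    "read_count_matrix",
    "write_count_matrix",
    "read_table",
    "write_table",
    "read_gmt",
    "write_gmt",
    "benjamini_hochberg",
    "bonferroni",
    "fisher_exact_2x2",
    "hypergeom_sf",
]

# Guide classes used throughout: genuine gene-targeting guides, non-targeting
# controls (match nothing in the genome), and safe-targeting controls (cut
# inert intronic/intergenic loci).
TARGETING = "targeting"
NON_TARGETING = "non_targeting"
SAFE_TARGETING = "safe_targeting"


@dataclass
class CountMatrix:
    """Sparse UMI count matrix, cells x genes.

    Attributes
    ----------
    cell_ids : list of str
        Unique cell barcodes (row labels).
    gene_ids : list of str
        Unique gene symbols (column labels); case-sensitive.
    counts : scipy.sparse.csr_matrix
        Non-negative integer UMI counts with shape
        ``(len(cell_ids), len(gene_ids))``.
    """

    cell_ids: list[str]
    gene_ids: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n, g = self.counts.shape
        if n != len(self.cell_ids) or g != len(self.gene_ids):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell IDs are not unique")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene IDs are not unique")
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise ValueError("counts contain negative entries")
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts contain non-integer entries")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def total_umis(self) -> np.ndarray:
        """Per-cell total UMI count (n_i)."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Per-cell number of genes with at least one count."""
        return np.diff(self.counts.indptr)

    def subset_cells(self, keep: np.ndarray | list) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            [self.cell_ids[i] for i in keep],
            list(self.gene_ids),
            self.counts[keep],
        )


def read_count_matrix(
    mtx_path: str | Path, cells_path: str | Path, genes_path: str | Path
) -> CountMatrix:
    """Read an MTX + cell-ID + gene-ID triple into a :class:`CountMatrix`.

    On-disk orientation follows the community convention (genes x cells)
    unless a ``<mtx>.orientation.json`` sidecar declares ``cells_x_genes``;
    in memory the matrix is always cells x genes.
    """
    mtx_path = Path(mtx_path)
    mat = scipy.io.mmread(mtx_path)
    cells = Path(cells_path).read_text().split()
    genes = Path(genes_path).read_text().split()
    sidecar = mtx_path.with_suffix(mtx_path.suffix + ".orientation.json")
    orientation = "genes_x_cells"
    if sidecar.exists():
        orientation = json.loads(sidecar.read_text())["orientation"]
    if orientation == "genes_x_cells":
        mat = mat.T
    if mat.shape != (len(cells), len(genes)):
        raise ValueError(
            f"MTX shape {mat.shape} (as cells x genes) does not match ID files "
            f"({len(cells)} cells, {len(genes)} genes)"
        )
    return CountMatrix(cells, genes, sp.csr_matrix(mat))


def write_count_matrix(cm: CountMatrix, mtx_path: str | Path,
                       cells_path: str | Path, genes_path: str | Path) -> None:
    """Write genes x cells MTX plus ID files and an orientation sidecar."""
    mtx_path = Path(mtx_path)
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(cm.counts.T), field="integer")
    Path(cells_path).write_text("\n".join(cm.cell_ids) + "\n")
    Path(genes_path).write_text("\n".join(cm.gene_ids) + "\n")
    sidecar = mtx_path.with_suffix(mtx_path.suffix + ".orientation.json")
    sidecar.write_text(json.dumps({"orientation": "genes_x_cells"}) + "\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-gene metadata.

    ``sets`` maps a set name to a set of gene symbols; ``gene_metadata`` is
    an optional per-gene table (e.g. LOEUF decile, TADA FDR, inheritance
    evidence) indexed by gene symbol.
    """

    sets: dict[str, set[str]]
    gene_metadata: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets from GMT (name, description, genes... per line)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        sets[fields[0]] = set(g for g in fields[2:] if g)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, ""] + sorted(genes))
        for name, genes in collection.sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min over j >= i of p_(j) * m / j, clipped to 1, where p_(1) <=
    ... <= p_(m).  NaN inputs are rejected: untested hypotheses must be
    filtered out before correction, not carried as NaN.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-values; filter untested hypotheses first")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bonferroni(p: np.ndarray) -> np.ndarray:
    """Bonferroni-adjusted p-values."""
    p = np.asarray(p, dtype=float)
    return np.minimum(p * p.size, 1.0)


def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns ``(odds_ratio, p)``.  The odds ratio is the sample cross-ratio
    (a*d)/(b*c); when any cell is zero the Haldane-Anscombe correction adds
    0.5 to every cell so the ratio stays defined.  The p-value is the exact
    (conditional hypergeometric) probability from scipy, which is stable for
    counts up to ~1e7.
    """
    table = np.array([[a, b], [c, d]])
    if (table < 0).any():
        raise ValueError("contingency cells must be non-negative")
    _, p = _scipy_fisher(table, alternative=alternative)
    if (table == 0).any():
        a_, b_, c_, d_ = (x + 0.5 for x in (a, b, c, d))
    else:
        a_, b_, c_, d_ = a, b, c, d
    odds_ratio = (a_ * d_) / (b_ * c_)
    return float(odds_ratio), float(p)


def hypergeom_sf(overlap: int, universe: int, set_size: int, draws: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, set_size, draws)."""
    from scipy.stats import hypergeom

    return float(hypergeom.sf(overlap - 1, universe, set_size, draws))
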