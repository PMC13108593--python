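"""Guide read filtering and per-cell perturbation assignment.

Raw guide capture tables (cell barcode, guide, UMI barcode, read count) are
cleaned in two stages before assignment: a dataset-global dynamic
read-support threshold that discards weakly supported UMIs while losing at
most a fixed fraction of total reads, and a directional merge of UMI
barcodes within a small edit distance inside each (cell, guide) group.
Guides with at least ``min_umi`` surviving UMIs in a cell are assigned to
it; cells are classed as carrying none, a single, or multiple guides.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

__all__ = [
    "dynamic_read_threshold",
    "filter_reads",
    "collapse_umis",
    "assign_guides",
    "run_assignment",
    "GuideAssignment",
]

READ_COLUMNS = ["cell_barcode", "guide_id", "umi_barcode", "read_count"]


@dataclass
class GuideAssignment:
    """Per-cell assignment table plus the read threshold that produced it.

    ``table`` has one row per cell: cell_barcode, guides (``;``-joined,
    empty for none), n_guides, assignment_class in {none, single, multi}.
    ``per_guide`` has one row per retained (cell, guide) with its collapsed
    UMI count.
    """

    table: pd.DataFrame
    per_guide: pd.DataFrame
    read_threshold: int
    min_umi: int

    def single_guide_cells(self) -> pd.DataFrame:
        return self.table[self.table["assignment_class"] == "single"]


def _validate(reads: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in READ_COLUMNS if c not in reads.columns]
    if missing:
        raise ValueError(f"guide read table missing columns {missing}")
    if len(reads) and (reads["read_count"] < 1).any():
        raise ValueError("read_count must be >= 1")
    return reads


def dynamic_read_threshold(reads: pd.DataFrame, max_loss: float = 0.01) -> int:
    """Largest integer k such that dropping UMIs supported by fewer than k
    reads loses at most ``max_loss`` of total sequenced guide reads.

    The loss is non-decreasing in k and reaches 1 beyond the best-supported
    UMI, so the maximum exists and is at least 1 (k = 1 drops nothing).
    """
    _validate(reads)
    if len(reads) == 0:
        raise ValueError("empty guide read table")
    counts = np.sort(reads["read_count"].to_numpy())
    total = counts.sum()
    # cumulative reads held by UMIs with read_count < k, for k at each
    # distinct count boundary; scan candidate k values in ascending order
    distinct = np.unique(counts)
    cum = np.cumsum(counts)
    best = 1
    for k in distinct:
        # reads lost at threshold k: all UMIs with read_count < k
        pos = np.searchsorted(counts, k, side="left")
        lost = cum[pos - 1] if pos > 0 else 0
        if lost / total <= max_loss:
            best = int(k)
        else:
            break
    return best


def filter_reads(reads: pd.DataFrame, threshold: int) -> pd.DataFrame:
    """Drop UMIs supported by fewer than ``threshold`` reads."""
    return reads[reads["read_count"] >= threshold].reset_index(drop=True)


def collapse_umis(reads: pd.DataFrame, max_edit_distance: int = 2) -> pd.DataFrame:
    """Directionally merge UMI barcodes within each (cell, guide) group.

    UMIs are visited in descending read count (ties lexicographic); a UMI
    joins the first already-retained representative within Levenshtein
    distance ``max_edit_distance``, donating its reads, otherwise it becomes
    a representative itself.  Greedy, count-descending merging keeps the
    procedure deterministic and prevents chains of unrelated UMIs from
    coalescing.  Reads are conserved within every group.
    """
    _validate(reads)
    if len(reads) == 0:
        return reads.copy()
    out_cell: list[str] = []
    out_guide: list[str] = []
    out_umi: list[str] = []
    out_reads: list[int] = []
    grouped = reads.sort_values(
        ["cell_barcode", "guide_id", "read_count", "umi_barcode"],
        ascending=[True, True, False, True], kind="stable",
    ).groupby(["cell_barcode", "guide_id"], sort=True)
    for (cell, guide), grp in grouped:
        reps: list[str] = []
        rep_reads: dict[str, int] = {}
        for umi, n in zip(grp["umi_barcode"], grp["read_count"]):
            merged = False
            for rep in reps:
                d = edlib.align(umi, rep, task="distance",
                                k=max_edit_distance)["editDistance"]
                if d != -1:
                    rep_reads[rep] += int(n)
                    merged = True
                    break
            if not merged:
                reps.append(umi)
                rep_reads[umi] = int(n)
        for rep in reps:
            out_cell.append(cell)
            out_guide.append(guide)
            out_umi.append(rep)
            out_reads.append(rep_reads[rep])
    return pd.DataFrame({
        "cell_barcode": out_cell,
        "guide_id": out_guide,
        "umi_barcode": out_umi,
        "read_count": out_reads,
    })


def assign_guides(
    collapsed: pd.DataFrame,
    min_umi: int = 3,
    read_threshold: int = 1,
) -> GuideAssignment:
    """Assign guides with >= ``min_umi`` distinct collapsed UMIs per cell."""
    _validate(collapsed)
    if len(collapsed) == 0:
        empty = pd.DataFrame(columns=[
            "cell_barcode", "guides", "n_guides", "assignment_class"])
        per_guide = pd.DataFrame(columns=["cell_barcode", "guide_id", "n_umis"])
        return GuideAssignment(empty, per_guide, read_threshold, min_umi)
    umi_counts = (
        collapsed.groupby(["cell_barcode", "guide_id"], sort=True)
        .size().rename("n_umis").reset_index()
    )
    kept = umi_counts[umi_counts["n_umis"] >= min_umi]
    per_cell = (
        kept.groupby("cell_barcode", sort=True)["guide_id"]
        .agg(lambda g: ";".join(sorted(g))).rename("guides").reset_index()
    )
    all_cells = pd.DataFrame(
        {"cell_barcode": sorted(collapsed["cell_barcode"].unique())})
    table = all_cells.merge(per_cell, on="cell_barcode", how="left")
    table["guides"] = table["guides"].fillna("")
    table["n_guides"] = table["guides"].str.count(";").where(
        table["guides"] != "", -1) + 1
    table["assignment_class"] = np.select(
        [table["n_guides"] == 0, table["n_guides"] == 1],
        ["none", "single"], default="multi",
    )
    return GuideAssignment(table, kept.reset_index(drop=True),
                           read_threshold, min_umi)


def run_assignment(
    reads: pd.DataFrame,
    max_loss: float = 0.01,
    max_edit_distance: int = 2,
    min_umi: int = 3,
) -> GuideAssignment:
    """Full pipeline: dynamic threshold -> UMI collapse -> assignment."""
    k = dynamic_read_threshold(reads, max_loss)
    collapsed = collapse_umis(filter_reads(reads, k), max_edit_distance)
    return assign_guides(collapsed, min_umi=min_umi, read_threshold=k)
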