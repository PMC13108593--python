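"""Synthetic Perturb-seq dataset generator with ground truth.

Emulates the statistical structure a pooled in vivo CRISPR screen with a
single-nucleus transcriptomic readout produces: cell-type-structured
negative-binomial expression, a guide library of 4 guides per target plus
400 non-targeting (NT) and 400 safe-targeting (ST) controls with library
fractions, truncated-Poisson multiplicity of infection calibrated to a
target single-guide share, target knockdown, injected differential
expression programmes, cell-type-specific depletion implemented as thinning
of the cell-sampling probability, empty droplets drawn from the pooled
ambient profile, and guide reads with per-UMI read counts and UMI-barcode
substitution errors.

Every stochastic step flows from a single integer seed, so a configuration
plus seed is a complete, byte-reproducible description of a dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp

from .core import (
    CountMatrix,
    NON_TARGETING,
    SAFE_TARGETING,
    TARGETING,
    write_count_matrix,
    write_table,
)

__all__ = [
    "DegProgram",
    "DepletionEffect",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "calibrate_moi",
    "simulate_dataset",
    "default_fixture",
    "write_dataset",
]

_BASES = np.array(list("ACGT"))


@dataclass
class DegProgram:
    """A transcriptional programme attached to one perturbation target.

    Perturbed cells (any guide targeting ``target_gene``, in ``cell_types``
    or everywhere when None) have the mean expression of ``genes``
    multiplied by ``2**lfc``.  ``module`` labels targets that share a
    programme family, for planted-structure recovery checks.
    """

    target_gene: str
    genes: list[str]
    lfc: float
    cell_types: list[str] | None = None
    module: str | None = None


@dataclass
class DepletionEffect:
    """Cells carrying a guide for ``target_gene`` in ``cell_type`` are
    retained with probability ``odds_ratio`` (in (0, 1]); the realised
    observed/expected cell-count ratio then has expectation ``odds_ratio``,
    so the downstream fitness test should report ~1/odds_ratio."""

    target_gene: str
    odds_ratio: float
    cell_type: str | None = None  # None = every cell type


@dataclass
class SimulationConfig:
    # cell population
    n_cell_types: int = 2
    cells_per_type: int = 1000
    cell_types_per_neighborhood: int = 2
    n_animals: int = 4
    # expression model
    n_genes: int = 200
    depth_per_cell: float = 3000.0
    gene_mean_sigma: float = 1.0       # log-normal spread of gene means
    type_effect_sigma: float = 0.35    # per-type log-normal wobble on means
    nb_dispersion: float = 2.0         # NB shape; var = mu + mu^2/theta
    size_factor_sigma: float = 0.25    # per-cell depth log-normal sigma
    # guide library
    n_target_genes: int = 20
    guides_per_gene: int = 4
    n_non_targeting: int = 400
    n_safe_targeting: int = 400
    class_mass: tuple[float, float, float] | None = None  # (targ, NT, ST)
    dirichlet_concentration: float | None = 200.0
    # multiplicity of infection
    moi_lambda: float | None = None    # None -> calibrate from single share
    target_single_share: float = 0.5
    # perturbation effects
    knockdown_fraction: float = 0.18
    deg_programs: list[DegProgram] = field(default_factory=list)
    depletion_effects: list[DepletionEffect] = field(default_factory=list)
    # guide read model
    umi_lambda: float = 6.0
    reads_per_umi_mean: float = 10.0
    reads_per_umi_dispersion: float = 4.0
    umi_error_rate: float = 0.01
    umi_length: int = 8
    min_umi_for_calibration: int = 3
    # droplets
    empty_droplet_fraction: float = 0.05
    empty_depth_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.knockdown_fraction <= 1.0:
            raise ValueError("knockdown_fraction must lie in [0, 1]")
        if not 0.0 <= self.empty_droplet_fraction < 1.0:
            raise ValueError("empty_droplet_fraction must lie in [0, 1)")
        for eff in self.depletion_effects:
            if not 0.0 < eff.odds_ratio <= 1.0:
                raise ValueError("depletion odds ratios must lie in (0, 1]")
        for attr in ("depth_per_cell", "umi_lambda", "reads_per_umi_mean"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")

    @property
    def cell_type_names(self) -> list[str]:
        return [f"CT{t}" for t in range(self.n_cell_types)]

    def neighborhood_of(self, cell_type: str) -> str:
        t = int(cell_type[2:])
        return f"NB{t // self.cell_types_per_neighborhood}"


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    true_guides: dict[str, list[str]]            # cell -> true guide IDs
    empty_cells: list[str]
    depletion_or: dict[str, float]               # "gene|cell_type" -> OR
    knockdown_fraction: float
    program_effects: dict[str, dict[str, float]]  # target -> {gene: lfc}
    module_of_target: dict[str, str]             # target -> planted module
    ambient_profile: list[float]                 # pooled p_g used for empties

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    annotations: pd.DataFrame
    guide_reads: pd.DataFrame
    library: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig


def calibrate_moi(
    target_single_share: float = 0.5,
    umi_lambda: float = 6.0,
    min_umi: int = 3,
) -> float:
    """Poisson MOI rate lambda such that among cells with >=1 *detected*
    guide the expected single-guide share equals ``target_single_share``.

    Detection of a carried guide requires at least ``min_umi`` captured UMIs
    (UMIs per guide ~ Poisson(umi_lambda)), so detected guide counts are a
    thinned Poisson with rate ``lambda * d``; we solve for the effective
    rate m with m e^-m / (1 - e^-m) = share and divide out the thinning.
    """
    from scipy.stats import poisson

    if not 0 < target_single_share < 1:
        raise ValueError("target_single_share must lie in (0, 1)")
    d = float(poisson.sf(min_umi - 1, umi_lambda))

    def gap(m: float) -> float:
        return m * np.exp(-m) / (1 - np.exp(-m)) - target_single_share

    m = scipy.optimize.brentq(gap, 1e-6, 30.0)
    return float(m / d)


def build_library(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Guide library table: guide_id, target_gene, guide_class,
    library_fraction (sums to 1)."""
    targets = _target_genes(config)
    rows: list[tuple[str, str, str]] = []
    for gene in targets:
        for j in range(config.guides_per_gene):
            rows.append((f"{gene}_g{j + 1}", gene, TARGETING))
    for i in range(config.n_non_targeting):
        rows.append((f"NT_{i + 1:03d}", "", NON_TARGETING))
    for i in range(config.n_safe_targeting):
        rows.append((f"ST_{i + 1:03d}", "", SAFE_TARGETING))
    lib = pd.DataFrame(rows, columns=["guide_id", "target_gene", "guide_class"])

    n_targ = len(targets) * config.guides_per_gene
    counts = {
        TARGETING: n_targ,
        NON_TARGETING: config.n_non_targeting,
        SAFE_TARGETING: config.n_safe_targeting,
    }
    total = sum(counts.values())
    if config.class_mass is None:
        mass = {k: v / total for k, v in counts.items()}
    else:
        mt, mn, ms = config.class_mass
        s = mt + mn + ms
        mass = {TARGETING: mt / s, NON_TARGETING: mn / s, SAFE_TARGETING: ms / s}
    frac = np.empty(len(lib))
    for cls, n in counts.items():
        idx = lib.index[lib["guide_class"] == cls]
        if config.dirichlet_concentration is None:
            w = np.full(n, 1.0 / n)
        else:
            w = rng.dirichlet(np.full(n, config.dirichlet_concentration))
        frac[idx] = w * mass[cls]
    lib["library_fraction"] = frac / frac.sum()
    return lib


def _target_genes(config: SimulationConfig) -> list[str]:
    """Targets are the highest-expressed genes, mirroring a screen designed
    around an expression-weighted rubric (gene means are seed-determined,
    so the ranking is reproducible)."""
    means = _base_gene_means(config)
    order = np.argsort(-means, kind="stable")[: config.n_target_genes]
    return [f"g{i:04d}" for i in sorted(order)]


def _base_gene_means(config: SimulationConfig) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    mu = rng.lognormal(mean=0.0, sigma=config.gene_mean_sigma, size=config.n_genes)
    return mu / mu.sum() * config.depth_per_cell


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate counts, annotations, guide reads, library, and ground truth."""
    root = np.random.SeedSequence([config.seed, 7])
    rngs = [np.random.default_rng(s) for s in root.spawn(6)]
    rng_lib, rng_cells, rng_expr, rng_reads, rng_empty, rng_misc = rngs

    gene_ids = [f"g{i:04d}" for i in range(config.n_genes)]
    library = build_library(config, rng_lib)
    guide_ids = library["guide_id"].to_numpy()
    fractions = library["library_fraction"].to_numpy()
    guide_target = dict(zip(library["guide_id"], library["target_gene"]))
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    # per-type mean vectors: shared log-normal baseline times a per-type wobble
    base = _base_gene_means(config)
    type_means = []
    for _ in range(config.n_cell_types):
        wobble = rng_expr.lognormal(0.0, config.type_effect_sigma, config.n_genes)
        mu = base * wobble
        type_means.append(mu / mu.sum() * config.depth_per_cell)
    type_means = np.asarray(type_means)

    moi = config.moi_lambda
    if moi is None:
        moi = calibrate_moi(
            config.target_single_share, config.umi_lambda,
            config.min_umi_for_calibration,
        )

    # effect lookups
    kd = config.knockdown_fraction
    prog_by_target: dict[str, list[DegProgram]] = {}
    for prog in config.deg_programs:
        prog_by_target.setdefault(prog.target_gene, []).append(prog)
    depl: dict[tuple[str, str], float] = {}
    for eff in config.depletion_effects:
        types = config.cell_type_names if eff.cell_type is None else [eff.cell_type]
        for ct in types:
            depl[(eff.target_gene, ct)] = eff.odds_ratio

    # ---- sample cells -----------------------------------------------------
    # vector-draw transduction events with replacement, then collapse
    # duplicate guide copies within a cell to one identity
    cell_type_col: list[str] = []
    guide_sets: list[list[str]] = []
    for ct in config.cell_type_names:
        ks = rng_cells.poisson(moi, size=config.cells_per_type)
        draws = rng_cells.choice(len(guide_ids), size=int(ks.sum()), p=fractions)
        offsets = np.concatenate([[0], np.cumsum(ks)])
        for c in range(config.cells_per_type):
            idx = draws[offsets[c]:offsets[c + 1]]
            guides = [guide_ids[j] for j in sorted(set(idx.tolist()))]
            # depletion as thinning of the cell-sampling probability
            keep = 1.0
            for g in guides:
                tgt = guide_target[g]
                if tgt:
                    keep *= depl.get((tgt, ct), 1.0)
            if keep < 1.0 and rng_cells.random() >= keep:
                continue
            cell_type_col.append(ct)
            guide_sets.append(guides)

    # each barcode is independently an empty droplet; empties keep the slot
    # (cell type label is meaningless for them but recorded for bookkeeping)
    n_total_planned = len(cell_type_col)
    empty_flags = rng_empty.random(n_total_planned) < config.empty_droplet_fraction

    cell_ids = [f"cell{i:06d}" for i in range(n_total_planned)]
    animals = [f"A{(i % config.n_animals) + 1}" for i in range(n_total_planned)]

    # pooled ambient profile for empties: type-mix weighted mean expression
    pooled = type_means.mean(axis=0)
    p_g = pooled / pooled.sum()

    # ---- expression counts ------------------------------------------------
    theta = config.nb_dispersion
    size_factors = rng_expr.lognormal(0.0, config.size_factor_sigma, n_total_planned)
    rows: list[sp.csr_matrix] = []
    chunk = 4000
    type_idx = np.array([int(ct[2:]) for ct in cell_type_col])
    # per-cell mean adjustments from perturbations
    for start in range(0, n_total_planned, chunk):
        stop = min(start + chunk, n_total_planned)
        mean_block = type_means[type_idx[start:stop]].astype(np.float64).copy()
        for local, i in enumerate(range(start, stop)):
            if empty_flags[i]:
                continue
            ct = cell_type_col[i]
            for g in guide_sets[i]:
                tgt = guide_target[g]
                if not tgt:
                    continue
                mean_block[local, gene_index[tgt]] *= 1.0 - kd
                for prog in prog_by_target.get(tgt, ()):
                    if prog.cell_types is None or ct in prog.cell_types:
                        idx = [gene_index[x] for x in prog.genes]
                        mean_block[local, idx] *= 2.0 ** prog.lfc
        mean_block *= size_factors[start:stop, None]
        lam = rng_expr.gamma(theta, mean_block / theta)
        block = rng_expr.poisson(lam)
        # overwrite empty droplets with multinomial ambient draws
        for local, i in enumerate(range(start, stop)):
            if empty_flags[i]:
                n_i = max(1, int(rng_empty.lognormal(
                    np.log(config.depth_per_cell * config.empty_depth_scale),
                    config.size_factor_sigma)))
                block[local] = rng_empty.multinomial(n_i, p_g)
        rows.append(sp.csr_matrix(block))
    counts = sp.vstack(rows, format="csr") if rows else sp.csr_matrix(
        (0, config.n_genes), dtype=np.int64)
    cm = CountMatrix(cell_ids, gene_ids, counts)

    # ---- guide reads ------------------------------------------------------
    reads = _simulate_guide_reads(
        config, rng_reads, cell_ids, guide_sets, empty_flags)

    # ---- annotations & truth ---------------------------------------------
    true_guides = {
        cid: guide_sets[i]
        for i, cid in enumerate(cell_ids)
        if not empty_flags[i] and guide_sets[i]
    }
    n_true = np.array([
        0 if empty_flags[i] else len(guide_sets[i])
        for i in range(n_total_planned)
    ])
    ann = pd.DataFrame({
        "cell_id": cell_ids,
        "animal_id": animals,
        "cell_type": cell_type_col,
        "neighborhood": [config.neighborhood_of(ct) for ct in cell_type_col],
        "n_genes_detected": cm.genes_detected(),
        "total_umis": cm.total_umis(),
        "true_multiplicity": n_true,
        "is_empty_truth": empty_flags,
    })

    truth = GroundTruth(
        true_guides=true_guides,
        empty_cells=[cid for i, cid in enumerate(cell_ids) if empty_flags[i]],
        depletion_or={f"{g}|{ct}": r for (g, ct), r in depl.items()},
        knockdown_fraction=kd,
        program_effects=_merge_program_effects(config.deg_programs),
        module_of_target={
            p.target_gene: p.module for p in config.deg_programs
            if p.module is not None
        },
        ambient_profile=[float(x) for x in p_g],
    )
    return SimulatedDataset(cm, ann, reads, library, truth, config)


def _merge_program_effects(programs: list[DegProgram]) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for p in programs:
        eff = out.setdefault(p.target_gene, {})
        for g in p.genes:
            eff[g] = eff.get(g, 0.0) + p.lfc
    return out


def _simulate_guide_reads(
    config: SimulationConfig,
    rng: np.random.Generator,
    cell_ids: list[str],
    guide_sets: list[list[str]],
    empty_flags: np.ndarray,
) -> pd.DataFrame:
    L = config.umi_length
    mean_extra = max(config.reads_per_umi_mean - 1.0, 1e-9)
    theta_r = config.reads_per_umi_dispersion
    recs: list[tuple[str, str, str, int]] = []
    for i, cid in enumerate(cell_ids):
        if empty_flags[i]:
            continue
        for g in guide_sets[i]:
            n_umi = rng.poisson(config.umi_lambda)
            if n_umi == 0:
                continue
            codes = rng.integers(0, 4, size=(n_umi, L))
            lam = rng.gamma(theta_r, mean_extra / theta_r, size=n_umi)
            n_reads = 1 + rng.poisson(lam)
            n_err = rng.binomial(n_reads, config.umi_error_rate)
            for u in range(n_umi):
                bc = "".join(_BASES[codes[u]])
                good = int(n_reads[u] - n_err[u])
                if good > 0:
                    recs.append((cid, g, bc, good))
                for _ in range(int(n_err[u])):
                    pos = rng.integers(0, L)
                    sub = (codes[u, pos] + rng.integers(1, 4)) % 4
                    mut = codes[u].copy()
                    mut[pos] = sub
                    recs.append((cid, g, "".join(_BASES[mut]), 1))
    reads = pd.DataFrame(
        recs, columns=["cell_barcode", "guide_id", "umi_barcode", "read_count"])
    if len(reads):
        # identical (cell, guide, umi) rows can arise from error collisions
        reads = (
            reads.groupby(["cell_barcode", "guide_id", "umi_barcode"],
                          as_index=False, sort=True)["read_count"].sum()
        )
    return reads


def default_fixture(scale: str = "tiny", seed: int = 0) -> SimulationConfig:
    """Reference configurations: ``tiny`` (~2,000 cells, 200 genes, 20
    targets; fast enough for unit tests) and ``desk`` (~20,000 cells, 2,000
    genes, 50 targets; the null-calibration scale)."""
    if scale == "tiny":
        return SimulationConfig(
            n_cell_types=2, cells_per_type=1000, n_genes=200,
            n_target_genes=20, depth_per_cell=1500.0, seed=seed,
        )
    if scale == "desk":
        return SimulationConfig(
            n_cell_types=2, cells_per_type=10000, n_genes=2000,
            n_target_genes=50, depth_per_cell=3000.0, seed=seed,
        )
    raise ValueError(f"unknown fixture scale {scale!r}")


def recovery_fixture(seed: int = 0) -> SimulationConfig:
    """Effect-recovery study conditions: 24,000 cells in two cell types,
    2,000 genes, three planted 4-perturbation modules with 50-gene
    programmes at |LFC| = 1 (signs split within each module, ~83% pairwise
    gene overlap inside a module), five depletion-only targets at odds
    ratio 0.3, and a library weighted so each target collects ≈300
    single-guide cells against a ≈2,800-cell non-targeting pool."""
    cfg = SimulationConfig(
        n_cell_types=2, cells_per_type=12000, n_genes=2000,
        n_target_genes=17, depth_per_cell=3000.0,
        class_mass=(0.646, 0.340, 0.014), seed=seed,
    )
    targets = _target_genes(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    # programme genes drawn from the expressed half of the transcriptome,
    # excluding the targets themselves
    means = _base_gene_means(cfg)
    expressed = np.flatnonzero(means >= np.median(means))
    candidates = [f"g{i:04d}" for i in expressed]
    candidates = [g for g in candidates if g not in targets]
    programs: list[DegProgram] = []
    pool_size, program_size = 60, 50
    picked = rng.choice(len(candidates), size=3 * pool_size, replace=False)
    for m in range(3):
        pool = [candidates[i] for i in picked[m * pool_size:(m + 1) * pool_size]]
        signs = np.where(np.arange(pool_size) % 2 == 0, 1.0, -1.0)
        for t in range(4):
            sel = np.sort(rng.choice(pool_size, size=program_size, replace=False))
            target = targets[m * 4 + t]
            for sign in (1.0, -1.0):
                genes = [pool[i] for i in sel if signs[i] == sign]
                programs.append(DegProgram(
                    target_gene=target, genes=genes, lfc=sign,
                    module=f"module_{'ABC'[m]}"))
    depletions = [
        DepletionEffect(target_gene=g, odds_ratio=0.3)
        for g in targets[12:17]
    ]
    cfg.deg_programs = programs
    cfg.depletion_effects = depletions
    return cfg


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, str]:
    """Write the dataset in the canonical on-disk formats; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": str(outdir / "counts.mtx"),
        "cells": str(outdir / "cells.txt"),
        "genes": str(outdir / "genes.txt"),
        "annotations": str(outdir / "annotations.tsv"),
        "guide_reads": str(outdir / "guide_reads.tsv"),
        "library": str(outdir / "library.tsv"),
        "ground_truth": str(outdir / "ground_truth.json"),
    }
    write_count_matrix(ds.counts, paths["mtx"], paths["cells"], paths["genes"])
    write_table(ds.annotations, paths["annotations"])
    write_table(ds.guide_reads, paths["guide_reads"])
    write_table(ds.library, paths["library"])
    ds.truth.to_json(paths["ground_truth"])
    return paths
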