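# perturbatlas

Analysis stack for pooled **in vivo Perturb-seq** screens: experiments in
which a CRISPR guide library is delivered to a whole tissue (here modeled
on a brain-wide AAV screen), nuclei are profiled by single-cell RNA-seq,
and each nucleus's captured guide RNA links its transcriptome to a genetic
perturbation. The package takes a sparse cell × gene UMI count matrix, a
raw guide-read table and the guide library's sequencing fractions, and
produces perturbation assignments, cell-level QC, per-cell-type fitness
(depletion) calls, differential expression with an empirical
false-discovery calibration, perturbation-similarity maps, and
disease-gene enrichment statistics. A first-class synthetic-data generator
emits datasets with the same statistical structure plus ground truth, so
every stage is testable end to end.

## The statistics at the core

- **Guide assignment.** Guide UMIs are cleaned by (1) a dataset-global
  dynamic threshold — the largest integer *k* such that discarding UMIs
  with fewer than *k* reads loses ≤ 1% of total guide reads — and (2)
  directional merging of UMI barcodes within Levenshtein distance 2 inside
  each (cell, guide) group. Guides with ≥ 3 surviving UMIs are assigned;
  cells are classed none / single / multi.
- **Ambient score.** For cell *i* with depth *n<sub>i</sub>* and pooled
  gene proportions *p<sub>g</sub>*:
  MSE<sub>i</sub> = (1/G) Σ<sub>g</sub> (x<sub>ig</sub> − p<sub>g</sub>n<sub>i</sub>)²,
  E[MSE<sub>i</sub>] = (1/G) Σ<sub>g</sub> n<sub>i</sub>p<sub>g</sub>(1 − p<sub>g</sub>),
  ambientScore<sub>i</sub> = ln MSE<sub>i</sub> − ln E[MSE<sub>i</sub>].
  Empty-droplet-like cells peak at 0 and are removed below a threshold
  (default 0.09); cells with < 2000 detected genes are removed outright.
- **Library-normalized relative fitness test.** Per guide and cell type,
  Fisher's exact test on [[A, B], [C, D]] with A = N<sub>C</sub>·f<sub>P</sub>
  (expected cells from the AAV library fraction), B = observed, C/D the
  same for the pooled non-targeting controls. OR = (A·D)/(B·C) > 1.2 with
  BH FDR < 0.05 in ≥ 2 of 4 guides flags a gene-level fitness defect.
- **Differential expression.** Single-guide cells only; every perturbation
  is compared against the pooled 400-guide non-targeting control with a
  two-sided Wilcoxon rank-sum test per gene on CP10K·log1p values (genes
  expressed in ≥ 10 cells; groups ≥ 20 cells; BH within each
  perturbation × cell-type family). The 400 safe-targeting guides are
  partitioned into 100 pseudo-genes of 4 and run through the identical
  analysis; the ratio of their mean DEG count to the targeting mean is an
  empirical FDR estimate.
- **Perturbation similarity.** Per cell type: CP10K → log1p → 2000 HVGs →
  z-scale → 50 PCs; pairwise energy distance with a label-permutation
  test; effect vectors (mean embedding of perturbed cells minus control
  mean) compared by cosine similarity and clustered hierarchically.
- **Enrichment.** One-sided Fisher / hypergeometric enrichment of DEG sets
  against disorder gene sets with fold enrichment FE = observed/expected,
  plus a 1,000-draw expression-quantile-matched bootstrap null (median and
  95% empirical CI), DEG-burden matrices, and inheritance-mode consensus
  scores.

## Worked example

```python
from perturbatlas.simulate import default_fixture, simulate_dataset
from perturbatlas.guides import run_assignment
from perturbatlas.qc import filter_cells
from perturbatlas.depletion import run_depletion

ds = simulate_dataset(default_fixture("tiny", seed=0))
asg = run_assignment(ds.guide_reads)         # dynamic k, UMI collapse, >=3 UMIs
qc = filter_cells(ds.counts, min_genes=50)   # tiny fixture has 200 genes

bearing = asg.table[asg.table["assignment_class"] != "none"]
print(f"read threshold k = {asg.read_threshold}")
print(f"single-guide share = {(bearing['assignment_class'] == 'single').mean():.3f}")
print(f"QC pass rate       = {qc['qc_pass'].mean():.3f}")

keep = set(qc.loc[qc["qc_pass"], "cell_id"])
per_guide, per_gene = run_depletion(
    asg.table[asg.table["cell_barcode"].isin(keep)],
    ds.annotations, ds.library, groupby="neighborhood")
print(f"depleted gene calls = {int(per_gene['gene_call'].sum())} "
      f"(no depletion was injected)")
```

Output:

```
read threshold k = 1
single-guide share = 0.509
QC pass rate       = 0.966
depleted gene calls = 0 (no depletion was injected)
```

The read threshold settles at 1 because, at the default 1% UMI-barcode
error rate, error reads alone already account for ~1% of total reads, so
no read-support cut can be taken without exceeding the loss budget — the
edit-distance-2 collapse stage absorbs those errors instead. The
single-guide share lands on the ~50% the guide-dose calibration targets,
and with no injected depletion the fitness test calls nothing.

There is also a CLI (`perturbatlas simulate|assign-guides|qc|depletion|de|run`)
and a YAML-configured pipeline (`perturbatlas run config.yaml`) that writes
every stage's table plus a provenance manifest.

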