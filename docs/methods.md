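# Methods

This note documents the statistical models implemented in `perturbatlas`,
the choices made where conventions were genuinely open, what the synthetic
data generator does and does not emulate, and the conditions under which
the package's reference studies are run.

## Guide assignment

Raw guide capture is a table of (cell barcode, guide, UMI barcode, read
count). Two error processes dominate: PCR/sequencing errors that mint
spurious low-read UMIs with mutated barcodes, and ambient/chimeric reads.
Cleaning proceeds in two stages:

1. **Dynamic read threshold.** The threshold is the largest integer k such
   that discarding UMIs supported by fewer than k reads removes at most
   `max_loss` (default 1%) of all sequenced guide reads. The loss is a
   non-decreasing step function of k that only changes at observed read
   counts, so the maximum is found by scanning distinct counts. One global
   threshold is computed per dataset: the loss budget is defined against
   total sequenced reads, not per cell.
2. **UMI collapse.** Within each (cell, guide) group, UMIs are visited in
   descending read count (ties broken lexicographically) and merged into
   the first already-retained representative within Levenshtein distance
   ≤ 2 (`edlib`), donating their reads; otherwise they found a new
   representative. This greedy directional scheme (the convention used by
   UMI-tools-style deduplication) is deterministic and cannot chain two
   distant UMIs through an intermediate. Levenshtein rather than Hamming
   distance is used — "edit distance" in the broad sense — and the radius
   is configurable.

Guides with at least `min_umi = 3` surviving UMIs in a cell are assigned;
cells are classed `none`/`single`/`multi` by assigned-guide count. Only
single-guide cells enter depletion and DE analyses, because only they give
an unambiguous genotype–phenotype link.

Note an interaction worth knowing: when the UMI-barcode error rate is at
or above the loss budget (1% and 1% by default), no read threshold above 1
is admissible — error reads are themselves ~1% of the total — and the
collapse stage does all the cleaning. The threshold engages when reads per
UMI are deep and concentrated (few genuine single-read UMIs).

## Cell QC: the ambient score

Let x_ig be the UMI count of gene g in cell i, n_i the cell's depth, and
p_g the pooled proportion of counts for gene g. Under the null that a
cell's contents are a random multinomial draw of n_i UMIs from the pooled
background,

    MSE_i    = (1/G) Σ_g (x_ig − p_g n_i)²
    E[MSE_i] = (1/G) Σ_g n_i p_g (1 − p_g)
    score_i  = ln MSE_i − ln E[MSE_i]

E[MSE_i] is exactly the multinomial expectation of MSE_i, so
background-indistinguishable cells (empty droplets, severe ambient
contamination) concentrate at score 0, while any genuine cell-type
structure inflates MSE above its null expectation and pushes the score
up. Cells **below** the threshold (default 0.09) are removed: the filter
discards the peak at zero and keeps cells that demonstrably differ from
the background. A cell with MSE = 0 has score −∞ — a profile identical to
the scaled background — and is removed with the rest of the ambient peak.
Natural log is used; since the score is a log-ratio, only the threshold's
scale depends on the base, and the default is documented as natural-log
scale.

Choices: p_g is computed on the cells that survive the detected-genes
filter (default ≥ 2000 genes), before ambient filtering — the background
is estimated from the same data being filtered, and the order is fixed for
reproducibility. The threshold's sharpness depends on G: with thousands of
genes the null score distribution is tight (sd ~0.02 at n_i ≈ 3000 in the
synthetic fixtures); with under a few hundred genes it widens and the 0.09
default is less specific. Doublet flags are accepted as an input column
from upstream tools, not recomputed; cluster-level multiplet removal
(which needs a trained embedding) is out of scope.

## Library-normalized relative fitness test

A perturbation that impairs survival or maintenance of a cell type is
recovered below its library expectation there. For guide P in cell group
C with N_C single-guide cells:

    A = round(N_C · f_P)      expected perturbation cells
    B = observed perturbation cells
    C = round(N_C · f_NTC)    expected non-targeting cells
    D = observed non-targeting cells

where f_P is P's AAV library fraction and f_NTC the summed fraction of all
non-targeting guides (D counts cells assigned any single NT guide). A
two-sided Fisher exact test is run on [[A, B], [C, D]]; the odds ratio is
oriented as (A·D)/(B·C) so OR > 1 means under-recovery relative to
controls, and OR > 1.2 with BH FDR < 0.05 (BH across all guide × group
pairs) marks a significant guide. A gene × group pair is called depleted
only when ≥ 2 of its 4 guides individually pass both criteria — the
guide-consistency rule that guards against single-guide off-target
artefacts. Expected counts are rounded to integers because the exact test
needs integer tables; effect sizes (log2 of observed fraction over library
fraction) use unrounded expectations. The odds ratio is the sample
cross-ratio with the Haldane–Anscombe 0.5 correction on zero cells — a
convention chosen because the test is used for thresholding (OR > 1.2)
and must stay defined at zeros; the convention is recorded in the output.

## Differential expression and empirical FDR

Within each cell group, genes are filtered to those expressed in ≥ 10 of
the group's cells; the group's counts are normalized to CP10K and log1p
transformed; and every perturbation with ≥ 20 single-guide cells is
compared against the pooled non-targeting control (all 400 NT guides
aggregated; also ≥ 20 cells) with a two-sided Wilcoxon rank-sum test per
gene. scipy's implementation is used with its exact small-sample path
when applicable and the tie-corrected normal approximation otherwise;
genes constant across both groups report p = 1. BH runs within each
perturbation × group gene family. The log2 fold change is defined on the
normalized means, lfc = log2((m_pert + ε)/(m_ctrl + ε)) with ε = 1e−9 —
the rank test itself is threshold-free, so the LFC definition only affects
effect-size reporting and gating.

The 400 safe-targeting guides (cutting inert loci) are randomly
partitioned into 100 pseudo-genes of 4 guides — structurally identical to
real targets — and pushed through the identical DE analysis. At any
significance threshold t, the empirical FDR is estimated as the mean DEG
count per pseudo-gene divided by the mean DEG count per targeting
perturbation, clipped to [0, 1]; this ratio-of-means estimator is a
deliberate, simple choice, and the per-pseudo-gene count distribution is
reported so users can substitute their own summary. On a no-effect
dataset the estimate is ≈ 1 (pseudo-genes and targets are exchangeable);
with real signal it falls well below 1.

## Perturbation similarity

Embedding: per cell group, CP10K → log1p → top-2000 highly variable genes
(scanpy's dispersion-based `seurat` flavor — deterministic and seedless) →
per-gene z-scaling → PCA to 50 components (ARPACK, fixed random state).

**Energy distance.** For cell sets X, Y in that space,
E = 2·mean d(x,y) − mean d(x,x′) − mean d(y,y′). The default pairwise
metric is squared Euclidean (the common single-cell e-distance
convention); plain Euclidean is available. Self-pairs are excluded from
the within-group means by default, giving a U-statistic whose expectation
is exactly zero for two samples of one distribution — it can dip negative
by sampling noise, and on a literally identical multiset E(X, X) is
slightly negative. The V-statistic convention (self-pairs included,
E(X, X) = 0 exactly, positively biased null) is available via
`unbiased=False`. Significance is by label permutation with the add-one
correction p = (1 + #{E_perm ≥ E_obs})/(1 + n_perm) and BH across pairs.
Perturbations enter the comparison only if they pass the effect gate:
≥ 5 DEGs at FDR < 0.05 with |LFC| strictly > 0.5.

**Effect vectors.** Per (perturbation, context): mean embedding of the
perturbation's cells minus the mean of control cells in the same context.
Vectors are compared by cosine similarity (zero vectors are flagged and
recorded as similarity 0), and the similarity matrix's rows are clustered
agglomeratively on Euclidean distances with average linkage — chosen for
robustness to unbalanced module sizes; the linkage is exported as Newick.
Effect vectors accept any embedding; the package default is the PCA
space (training a VAE latent space is out of scope, but externally
computed embeddings can be supplied).

**KNN imputation.** For de-noised visualisation matrices: iterating from
the coarsest to the finest level of a label hierarchy, each cell's values
are replaced by the mean of its k = 15 nearest same-group neighbours
(cosine metric, k capped at group size), each level computed on the
previous level's output.

## Enrichment analytics

DEG-burden matrices count DEGs at a stated FDR per perturbation (or per
gene category, summing member perturbations) and cell group; rows with
fewer than 10 total DEGs are excluded when the rule is active; log10(x+1)
is used for display (raw counts always retained) and per-row min–max
scaling is optional. Group comparisons of DEG totals use two-sided
Wilcoxon rank-sum tests (two groups) or Kruskal–Wallis followed by
pairwise rank-sum against a reference group, reported unadjusted with the
pairing recorded.

Gene-set enrichment is the one-sided (greater) Fisher / hypergeometric
test with FE = observed / expected overlap, expected =
|DEG|·|set ∩ universe| / |universe|, the universe being all genes tested
for DE in that context. A perturbation's own target gene is excluded from
its DEG list, and only queries with ≥ 20 unique DEGs are tested. Bonferroni
is used for cell-type-level screens, BH across targets otherwise.

The expression-matched bootstrap controls for expression bias: pool and
target genes are binned into expression quantiles (default 10 deciles),
and each of 1,000 bootstrap sets draws, per bin without replacement,
exactly the target set's bin count from non-target pool genes. FE is
recomputed per draw, yielding a median and 95% empirical CI per query;
an observed FE above the 97.5th matched percentile exceeds the
expression-matched background. Matched sets never contain target-set
genes, and bin counts are asserted on every draw.

LOEUF deciles 0–2 / 3–5 / 6–9 map to constrained / intermediate /
tolerant strata. Inheritance consensus scores sum configurable evidence
weights (exome-wide significance 10, FDR-level 5, LOEUF decile d
contributing 10·(1 − d/10), curated sources by evidence tier) into
dominant / recessive / X-linked scores; genes with dominance > 20 or
recessive > 10 (strict) are stratified by a median split, and evidence
strength is otherwise stratified into five quantiles of −log10(FDR).

## Target-design rubric

S = 10·w_c + 2·(w_a + w_b) + 0.2·E_p, with w_c the primary
disease-association weight, w_a/w_b secondary functional weights (binary
membership indicators by default; the per-category assignments are
configurable), and E_p the expression decile 1–10 (ascending rank,
stable ties). Selection is inclusive at the cutoff (S ≥ 3.8): the cutoff
is published without strictness, and inclusivity makes the boundary
reproducible.

## Synthetic data generator

The generator emulates the structure the analyses assume, with ground
truth for every injected effect:

- **Expression.** Per-cell-type mean vectors: a shared log-normal gene
  baseline (σ = 1) times per-type log-normal wobble (σ = 0.35), scaled to
  a target depth (3,000 UMIs/cell at desk scale); counts are negative
  binomial (gamma–Poisson, dispersion θ = 2) with per-cell log-normal size
  factors (σ = 0.25). This reproduces the overdispersion the rank-sum DE
  and the ambient score must tolerate.
- **Library.** 4 guides per target plus 400 non-targeting and 400
  safe-targeting controls; fractions are Dirichlet-sampled around uniform
  (concentration 200) with configurable per-class mass. Target genes are
  the highest-expressed genes — mirroring a screen designed around an
  expression-weighted rubric and keeping knockdown estimable.
- **Multiplicity.** Per-cell guide copies are Poisson; drawn guides
  deduplicate within a cell. The rate is calibrated so that the share of
  *detected* single-guide cells among guide-bearing cells hits a target
  (default 50%), folding in the capture model: a carried guide is detected
  when ≥ 3 of its Poisson(λ_umi = 6) UMIs survive, so the transduction
  rate is the calibrated detected rate divided by that detection
  probability.
- **Effects.** Knockdown multiplies the target's mean by (1 − 0.18) in
  perturbed cells — applied to the mean, preserving integer counts and the
  mean–variance relation. DEG programmes multiply affected-gene means by
  2^LFC. Depletion thins the cell-sampling probability: cells carrying a
  depleted (gene, cell type) combination are retained with probability
  equal to the configured odds ratio, so the realized contingency table's
  expected OR equals the configured value and recovery is analytically
  checkable.
- **Guide reads.** UMIs per captured guide ~ Poisson(6); reads per UMI ~
  1 + NB(mean 9, dispersion 4) — a deep, concentrated read distribution
  typical of dedicated guide libraries (≈1% genuine single-read UMIs);
  each read independently suffers a UMI-barcode substitution with
  probability 0.01, minting 1-read error UMIs one base away.
- **Droplets.** Each barcode is independently an empty droplet with
  probability 0.05; empties draw multinomially from the pooled profile at
  half depth — by construction they sit at ambient score 0.

Not emulated: batch or animal covariate effects on expression (animal IDs
are assigned but carry no signal), spatial structure, read-level FASTQ
error profiles, cross-guide ambient contamination, or doublets. Passing
tests therefore demonstrate correctness of the statistics under the
generative assumptions, not robustness to every artefact of real tissue
data.

## Reference studies and problem sizes

Two studies (in `perturbatlas.benchmarks`) are the package's calibration
and recovery evidence, also recomputed by `scripts/acceptance.py`:

- **Null calibration** — the `desk` fixture: 2 cell types × 10,000 cells,
  2,000 genes, 50 targets, no injected effects; DE and depletion run at
  the neighborhood resolution (both types share one neighborhood) so
  groups clear the 20-cell floor (~29 single cells per perturbation,
  ~2,900-cell NT pool, ~96,000 gene tests). Measured: Wilcoxon type-I
  error at α = 0.05; rank-sum comparison of pseudo-gene vs targeting DEG
  counts; depletion gene-level false calls; e-distance permutation size
  on 100 disjoint random splits of the NT pool (identical generative
  groups, independent across pairs); assignment identity accuracy and
  single-guide share; mean ambient score of true empties.
- **Parameter recovery** — 2 cell types × 12,000 cells, 2,000 genes, 17
  targets with elevated library fractions (≈300 single cells per target
  vs a ≈2,800-cell NT pool): 12 targets carry 50-gene programmes at
  |LFC| = 1 (signs split within each of three 4-target modules, ~83%
  pairwise within-module gene overlap, programme genes drawn from the
  expressed half of the transcriptome), 5 targets carry depletion at
  OR 0.3 (≈300 expected cells each, so per-guide Fisher tests are
  powered). Measured: depletion sensitivity, DE sensitivity and observed
  FDR against ground truth, LFC sign agreement, effect-vector module
  clustering (cut at 3, adjusted Rand index against planted modules),
  realized knockdown, and the expression-matched bootstrap's median FE
  under expression-independent random queries (≈1 by construction).

These sizes were chosen as the smallest at which every test is
well-powered and group-size floors are comfortably cleared; the whole
suite, including both studies, runs in about four minutes on one CPU.

## Numerical and degenerate-input conventions

- BH rejects NaN p-values (untested hypotheses must be filtered first);
  q-values are clipped to 1 and ties share q.
- Fisher tables must be non-negative integers; degenerate margins in the
  fitness test report OR 1, p 1 with a flag.
- `wilcoxon_de` reports p = 1 and lfc = 0 for genes constant across both
  groups.
- `deg_jaccard` of two empty sets is 0 (flagged in documentation rather
  than NaN).
- Cosine similarity of a zero effect vector is recorded as 0.
- All randomized procedures (simulation, pseudo-gene partition,
  permutation tests, bootstraps) take explicit integer seeds; the
  pipeline derives per-stage seeds from one global seed by hashing the
  stage name, so stages re-run in isolation reproduce themselves, and
  identically configured runs are byte-identical.

## Known limitations

- The ambient-score threshold default (0.09) presumes a transcriptome-
  scale gene panel; small panels broaden the null peak.
- The empirical-FDR estimator is a ratio of means; with very few tested
  pseudo-genes its variance is substantial.
- The depletion test conditions on the library fractions as known
  constants; uncertainty in the NGS library quantification is not
  propagated.
- Rank-sum DE ignores animal-level correlation; a pseudobulk or
  mixed-model extension would be needed for designs where animal effects
  are strong.
- The energy-distance permutation loop re-labels a precomputed distance
  matrix, so memory scales with the square of the two group sizes.
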