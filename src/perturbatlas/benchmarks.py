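"""End-to-end calibration and recovery studies on synthetic datasets.

Two reference studies exercise the whole stack under known truth:

* :func:`run_null_calibration` — a desk-scale dataset (~20k cells, 2,000
  genes, 50 targets) with *no* injected effects.  Every reported discovery
  is a false positive, so the study measures the type-I error of the
  Wilcoxon DE test, the exchangeability of targeting perturbations and
  safe-targeting pseudo-genes, the gene-level false-call count of the
  depletion test, and the size of the e-distance permutation test.

* :func:`run_parameter_recovery` — injected depletion (odds ratio 0.3),
  50-gene expression programmes at |LFC| = 1 organised into three planted
  4-perturbation modules, and the default 18% target knockdown.  The study
  measures how much of that truth the pipeline recovers: depletion
  sensitivity, DE sensitivity and observed FDR, sign agreement, module
  clustering accuracy, knockdown, and the behaviour of the
  expression-matched bootstrap under an expression-independent query.

Both return plain dictionaries of scalar metrics (plus the intermediate
tables under ``frames`` for inspection).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from sklearn.metrics import adjusted_rand_score

from . import diffexpr, similarity as sim_mod
from .depletion import run_depletion
from .enrichment import expression_matched_bootstrap
from .guides import run_assignment
from .qc import filter_cells
from .simulate import (
    SimulatedDataset,
    default_fixture,
    recovery_fixture,
    simulate_dataset,
)

__all__ = ["run_null_calibration", "run_parameter_recovery"]

# synthetic fixtures have 2,000 genes, so the detected-gene floor scales to
# a quarter of the transcriptome rather than the atlas default of 2,000
SYNTH_MIN_GENES = 500


def _assign_and_qc(ds: SimulatedDataset):
    asg = run_assignment(ds.guide_reads)
    qc = filter_cells(ds.counts, min_genes=SYNTH_MIN_GENES)
    return asg, qc


def run_null_calibration(seed: int = 0, n_edist_groups: int = 10,
                         n_permutations: int = 199) -> dict:
    ds = simulate_dataset(default_fixture("desk", seed=seed))
    asg, qc = _assign_and_qc(ds)

    # --- assignment fidelity ---------------------------------------------
    truth = ds.truth.true_guides
    singles = asg.table[asg.table["assignment_class"] == "single"]
    true_single = {c: g[0] for c, g in truth.items() if len(g) == 1}
    both = [c for c in singles["cell_barcode"] if c in true_single]
    guide_of = dict(zip(singles["cell_barcode"], singles["guides"]))
    identity_acc = float(np.mean([guide_of[c] == true_single[c] for c in both]))
    bearing = asg.table[asg.table["assignment_class"] != "none"]
    single_share = float(
        (bearing["assignment_class"] == "single").mean())

    # --- ambient score on true empties -----------------------------------
    empties = set(ds.truth.empty_cells)
    qc_emp = qc[qc["cell_id"].isin(empties) & qc["ambient_score"].notna()]
    empty_mean_score = float(qc_emp["ambient_score"].mean())
    empty_removed = float((~qc_emp["qc_pass"]).mean())

    # --- DE null calibration ---------------------------------------------
    cells = diffexpr.single_guide_cells(
        asg.table, ds.annotations, ds.library, qc=qc, groupby="neighborhood")
    pseudo = diffexpr.build_pseudo_genes(ds.library, seed=seed)
    de, _ = diffexpr.run_de(ds.counts, cells, pseudo_genes=pseudo)
    target_p = de.loc[de["perturbation_class"] == "target", "p"].to_numpy()
    type1 = float((target_p < 0.05).mean())

    deg_counts = (
        de.assign(is_deg=de["q"] < 0.05)
        .groupby(["perturbation", "perturbation_class"])["is_deg"].sum()
        .reset_index()
    )
    from scipy.stats import mannwhitneyu

    pseudo_counts = deg_counts.loc[
        deg_counts["perturbation_class"] == "pseudo", "is_deg"]
    target_counts = deg_counts.loc[
        deg_counts["perturbation_class"] == "target", "is_deg"]
    if pseudo_counts.nunique() <= 1 and target_counts.nunique() <= 1 and \
            set(pseudo_counts) == set(target_counts):
        exchange_p = 1.0  # identical constant distributions
    else:
        exchange_p = float(mannwhitneyu(
            pseudo_counts, target_counts, alternative="two-sided").pvalue)
    calib = diffexpr.calibrate_fdr(de)

    # --- depletion false calls -------------------------------------------
    _, per_gene = run_depletion(
        asg.table[asg.table["cell_barcode"].isin(
            set(qc.loc[qc["qc_pass"], "cell_id"]))],
        ds.annotations, ds.library, groupby="neighborhood")
    depl_false = int(per_gene["gene_call"].sum())

    # --- e-distance permutation size -------------------------------------
    # disjoint random splits of the non-targeting pool are identical
    # generative groups AND independent across pairs, so the rejection
    # rate is a clean binomial estimate of the test's size
    rng = np.random.default_rng(seed)
    group_cells = cells[cells["group"] == sorted(cells["group"].unique())[0]]
    emb = sim_mod.normalize_for_similarity(
        ds.counts, cell_ids=list(group_cells["cell_id"]), random_state=seed)
    nt_ids = group_cells.loc[
        group_cells["guide_class"] == "non_targeting", "cell_id"].to_numpy()
    nt_ids = rng.permutation(nt_ids)
    n_pairs = min(100, len(nt_ids) // 20)
    m = len(nt_ids) // (2 * n_pairs)
    pvals = []
    for i in range(n_pairs):
        a = nt_ids[2 * i * m:(2 * i + 1) * m]
        b = nt_ids[(2 * i + 1) * m:(2 * i + 2) * m]
        ed = sim_mod.edistance_test(
            {"a": emb.loc[a].to_numpy(), "b": emb.loc[b].to_numpy()},
            n_permutations=n_permutations, seed=seed + i)
        pvals.append(float(ed["p"].iloc[0]))
    pvals = np.array(pvals)
    edist_rejection = float((pvals <= 0.05).mean())

    return {
        "assigned_single_share": single_share,
        "guide_identity_accuracy": identity_acc,
        "empty_mean_ambient_score": empty_mean_score,
        "empty_removed_fraction": empty_removed,
        "wilcoxon_type1_at_005": type1,
        "n_null_gene_tests": int(len(target_p)),
        "pseudo_target_exchange_p": exchange_p,
        "empirical_fdr_at_005": float(
            calib.loc[calib["threshold"] == 0.05, "empirical_fdr"].iloc[0]),
        "depletion_false_gene_calls": depl_false,
        "n_depletion_gene_tests": int(len(per_gene)),
        "edistance_null_rejection_at_005": edist_rejection,
        "n_edistance_pairs": int(n_pairs),
        "frames": {"de": de, "deg_counts": deg_counts, "per_gene": per_gene,
                   "edist_pvals": pvals, "qc": qc, "calibration": calib,
                   "dataset": ds, "assignment": asg},
    }


def run_parameter_recovery(seed: int = 0, n_boot: int = 1000) -> dict:
    cfg = recovery_fixture(seed=seed)
    ds = simulate_dataset(cfg)
    asg, qc = _assign_and_qc(ds)
    keep = set(qc.loc[qc["qc_pass"], "cell_id"])
    asg_pass = asg.table[asg.table["cell_barcode"].isin(keep)]

    truth = ds.truth
    program_targets = sorted(truth.module_of_target)
    depleted = sorted({k.split("|")[0] for k in truth.depletion_or})

    # --- depletion sensitivity -------------------------------------------
    _, per_gene = run_depletion(
        asg_pass, ds.annotations, ds.library, groupby="neighborhood")
    calls = per_gene.set_index("target_gene")["gene_call"]
    depl_sens = float(np.mean([bool(calls.get(g, False)) for g in depleted]))
    depl_false = int(per_gene.loc[
        ~per_gene["target_gene"].isin(depleted), "gene_call"].sum())

    # --- DE recovery ------------------------------------------------------
    cells = diffexpr.single_guide_cells(
        asg_pass, ds.annotations, ds.library, qc=qc, groupby="neighborhood")
    de, _ = diffexpr.run_de(ds.counts, cells)
    de_t = de[de["perturbation_class"] == "target"]
    tp = fp = fn = 0
    sign_ok = sign_tot = 0
    for target in program_targets:
        eff = truth.program_effects.get(target, {})
        true_genes = set(eff) | {target}
        sub = de_t[de_t["perturbation"] == target]
        hits = sub[sub["q"] < 0.05]
        hit_genes = set(hits["gene"])
        tested = set(sub["gene"])
        tp += len(hit_genes & true_genes)
        fp += len(hit_genes - true_genes)
        fn += len((true_genes & tested) - hit_genes)
        for r in hits.itertuples():
            expected = eff.get(r.gene, -1.0 if r.gene == target else None)
            if expected is not None:
                sign_tot += 1
                sign_ok += (np.sign(r.lfc) == np.sign(expected))
    de_sens = tp / (tp + fn) if tp + fn else float("nan")
    de_fdr = fp / (tp + fp) if tp + fp else 0.0
    sign_agreement = sign_ok / sign_tot if sign_tot else float("nan")

    # --- knockdown --------------------------------------------------------
    kd_est = _knockdown_estimate(ds, cells)

    # --- module recovery via effect-vector clustering ---------------------
    group0 = sorted(cells["group"].unique())[0]
    gcells = cells[cells["group"] == group0].copy()
    gcells["perturbation"] = np.where(
        gcells["guide_class"] == "targeting", gcells["target_gene"], np.nan)
    emb = sim_mod.normalize_for_similarity(
        ds.counts, cell_ids=list(gcells["cell_id"]), random_state=seed)
    vec = sim_mod.compute_effect_vectors(emb, gcells)
    vec = vec.loc[[(p, group0) for p in program_targets]]
    cos = sim_mod.cosine_matrix(vec)
    Z, _ = sim_mod.cluster_similarity(cos)
    labels = sch.fcluster(Z, t=3, criterion="maxclust")
    planted = [truth.module_of_target[p] for p, _ in cos.index]
    ari = float(adjusted_rand_score(planted, labels))

    # --- expression-matched bootstrap under an independent query ----------
    rng = np.random.default_rng(seed)
    universe = set(de_t["gene"].unique())
    expression = pd.Series(
        np.asarray(ds.counts.counts.mean(axis=0)).ravel(),
        index=ds.counts.gene_ids).loc[sorted(universe)]
    uni = np.array(sorted(universe))
    target_set = set(rng.choice(uni, size=150, replace=False))
    queries = {
        f"random_{i}": set(rng.choice(uni, size=100, replace=False))
        for i in range(5)
    }
    boot = expression_matched_bootstrap(
        target_set, universe - target_set, expression, queries, universe,
        n_boot=n_boot, seed=seed)
    boot_median_fe = float(np.mean(list(boot.median_fe.values())))

    return {
        "depletion_sensitivity": depl_sens,
        "depletion_false_gene_calls": depl_false,
        "de_sensitivity": de_sens,
        "de_observed_fdr": de_fdr,
        "de_sign_agreement": sign_agreement,
        "mean_knockdown_fraction": kd_est,
        "module_ari": ari,
        "bootstrap_median_fe": boot_median_fe,
        "n_program_targets": len(program_targets),
        "n_depleted_targets": len(depleted),
        "frames": {"de": de, "per_gene": per_gene, "cosine": cos,
                   "effect_vectors": vec, "qc": qc, "dataset": ds},
    }


def _knockdown_estimate(ds: SimulatedDataset, cells: pd.DataFrame) -> float:
    """Mean fractional reduction of each target gene's CP10K expression in
    its perturbed cells relative to the non-targeting pool."""
    cell_index = {c: i for i, c in enumerate(ds.counts.cell_ids)}
    gene_index = {g: i for i, g in enumerate(ds.counts.gene_ids)}
    depth = ds.counts.total_umis().astype(float)
    depth[depth == 0] = 1.0
    targets = sorted(set(
        cells.loc[cells["guide_class"] == "targeting", "target_gene"]))
    ctrl_idx = np.array([
        cell_index[c] for c in
        cells.loc[cells["guide_class"] == "non_targeting", "cell_id"]])
    ests = []
    for t in targets:
        pert_idx = np.array([
            cell_index[c] for c in
            cells.loc[cells["target_gene"] == t, "cell_id"]])
        g = gene_index[t]
        cp_pert = (np.asarray(
            ds.counts.counts[pert_idx, g].todense()).ravel()
            / depth[pert_idx] * 1e4).mean()
        cp_ctrl = (np.asarray(
            ds.counts.counts[ctrl_idx, g].todense()).ravel()
            / depth[ctrl_idx] * 1e4).mean()
        if cp_ctrl > 0:
            ests.append(1.0 - cp_pert / cp_ctrl)
    return float(np.mean(ests))
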