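"""End-to-end synthetic studies: simulate -> PSI -> classify -> learn -> explain.

Two canned studies define the package's default synthetic conditions:

* :func:`recovery_study` — a mixed library (ΦN-terminal, W(-5) and random
  peptides) profiled in wild type and das1 with replicate sort-seq runs;
  measures how well PSI recovers planted stability, how reliably planted
  SCF/Das1-rule degrons are called stabilized in the mutant, and whether a
  +1-extension scan classifies a planted ΦN degron as a C-degron.
* :func:`motif_discovery_study` — a larger wild-type library used to train
  the stability classifier on PSI-derived labels, explain correctly
  predicted unstable peptides with permutation SHAP, cluster the
  attributions and select potential C-degron motif clusters.

Library compositions enrich the planted motifs well above their random
occurrence so that desk-scale runs contain enough degrons; everything else
(simulation depth, noise, thresholds) follows the package defaults.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import classify as dc
from . import features as ft
from . import interpret as si
from . import net as dn
from .psi import combine_replicates, compute_psi, differential_psi, filter_psi
from .synthetic import (
    GroundTruthModel,
    SortSimConfig,
    build_mutant_libraries,
    default_ground_truth,
    generate_library,
    simulate_sort_seq,
    true_stability,
)

#: a hydrophilic 12-mer ending in the ΦN dipeptide, used for the capping scan
CAPPING_WT = "GSTAQGSTQDIN"


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s % (2**31)) for s in np.random.SeedSequence(seed).generate_state(n)]


def build_mixed_library(
    n_phin: int, n_w5: int, n_random: int, length: int = 12, seed: int = 0
) -> list[str]:
    """ΦN-terminal + W(-5) + random peptides, unique across groups."""
    s1, s2, s3 = _child_seeds(seed, 3)
    phin = generate_library(
        "fixed_positions", length, n_phin,
        fixed={-2: set("ILMV"), -1: {"N"}}, seed=s1,
    )
    w5 = generate_library("fixed_positions", length, n_w5, fixed={-5: {"W"}}, seed=s2)
    rand = generate_library("random", length, n_random, seed=s3)
    seen: dict[str, None] = {}
    for p in phin + w5 + rand:
        seen.setdefault(p, None)
    return list(seen)


def das1_rule_degrons(lib: list[str], model: GroundTruthModel) -> set[str]:
    """Peptides destabilized by a das1-neutralized planted rule."""
    rules = [r for r in model.rules if "das1" in r.neutralized_by]
    return {p for p in lib if any(r.matches(p) for r in rules)}


def simulate_replicates(
    lib: list[str],
    genotype: str,
    model: GroundTruthModel,
    n_replicates: int,
    seed: int,
    n_cells: int = 500_000,
    reads_per_bin: int = 100_000,
) -> list[pd.DataFrame]:
    """PSI tables of ``n_replicates`` independent sort-seq simulations."""
    tables = []
    for rep_seed in _child_seeds(seed, n_replicates):
        cfg = SortSimConfig(n_cells=n_cells, reads_per_bin=reads_per_bin, seed=rep_seed)
        cm, scheme = simulate_sort_seq(lib, genotype, model, cfg)
        tables.append(compute_psi(cm, scheme))
    return tables


def recovery_study(
    seed: int = 0,
    n_phin: int = 150,
    n_w5: int = 100,
    n_random: int = 350,
    n_replicates: int = 3,
    n_cells: int = 500_000,
    reads_per_bin: int = 100_000,
    model: GroundTruthModel | None = None,
) -> dict:
    model = model or default_ground_truth()
    lib_seed, wt_seed, mut_seed, cap_seed = _child_seeds(seed, 4)
    lib = build_mixed_library(n_phin, n_w5, n_random, seed=lib_seed)

    wt_tables = simulate_replicates(lib, "wt", model, n_replicates, wt_seed, n_cells, reads_per_bin)
    das1_tables = simulate_replicates(lib, "das1", model, n_replicates, mut_seed, n_cells, reads_per_bin)
    wt_combined = combine_replicates(wt_tables)

    truth = pd.Series({p: true_stability(p, "wt", model) for p in lib})
    merged = filter_psi(wt_combined).set_index("peptide")["psi"].to_frame("psi")
    merged["truth"] = truth.loc[merged.index]
    rho = float(spearmanr(merged["psi"], merged["truth"]).statistic)

    diff = differential_psi(wt_tables, das1_tables)
    calls = dc.classify_dependence_table(diff)
    planted = das1_rule_degrons(lib, model)
    called = calls.set_index("peptide")["call"]
    planted_present = [p for p in planted if p in called.index]
    controls = [p for p in called.index if p not in planted]
    frac_sp = float(np.mean([called[p] in ("s", "p") for p in planted_present]))
    frac_n = float(np.mean([called[p] == "n" for p in controls]))

    das1_combined = combine_replicates(das1_tables)
    phin_rule = next(r for r in model.rules if r.name == "phiN_cterm")
    phin_peps = [p for p in lib if phin_rule.matches(p)]
    wt_psi_lookup = filter_psi(wt_combined).set_index("peptide")["psi"]
    mut_psi_lookup = filter_psi(das1_combined).set_index("peptide")["psi"]
    phin_mean_wt = float(wt_psi_lookup.reindex(phin_peps).mean())
    phin_mean_das1 = float(mut_psi_lookup.reindex(phin_peps).mean())

    # +1-extension capping scan of a planted ΦN degron, wild-type genotype
    ext_lib = build_mutant_libraries(CAPPING_WT)["extension"]
    cfg = SortSimConfig(n_cells=max(n_cells // 5, 10_000), reads_per_bin=reads_per_bin, seed=cap_seed)
    cm, scheme = simulate_sort_seq(ext_lib, "wt", model, cfg)
    ext_psi = compute_psi(cm, scheme)
    scan = dc.build_scan_matrix(ext_psi, CAPPING_WT, "extension")
    capping = dc.classify_cdegron_and_capping(scan)

    return {
        "library": lib,
        "model": model,
        "wt_tables": wt_tables,
        "das1_tables": das1_tables,
        "wt_combined": wt_combined,
        "das1_combined": das1_combined,
        "diff": diff,
        "calls": calls,
        "planted_das1_degrons": planted,
        "spearman_psi_truth": rho,
        "frac_planted_called_sp": frac_sp,
        "frac_controls_called_n": frac_n,
        "phin_mean_psi_wt": phin_mean_wt,
        "phin_mean_psi_das1": phin_mean_das1,
        "extension_scan": scan,
        "capping": capping,
    }


def motif_discovery_study(
    seed: int = 0,
    n_phin: int = 600,
    n_w5: int = 600,
    n_random: int = 1800,
    n_cells: int = 500_000,
    reads_per_bin: int = 100_000,
    n_per_class: int = 1000,
    n_explain: int = 200,
    n_background: int = 100,
    n_perm: int = 100,
    k_range=range(1, 9),
    model: GroundTruthModel | None = None,
) -> dict:
    model = model or default_ground_truth()
    lib_seed, sim_seed, split_seed, net_seed, shap_seed, km_seed = _child_seeds(seed, 6)
    lib = build_mixed_library(n_phin, n_w5, n_random, seed=lib_seed)

    cfg = SortSimConfig(n_cells=n_cells, reads_per_bin=reads_per_bin, seed=sim_seed)
    cm, scheme = simulate_sort_seq(lib, "wt", model, cfg)
    psis = filter_psi(compute_psi(cm, scheme))
    labels = pd.Series(
        np.where(psis["psi"] < 0.5, "unstable", "stable"), index=psis["peptide"]
    )

    n_per_class = min(n_per_class, int((labels == "unstable").sum()), int((labels == "stable").sum()))
    splits = dn.split_dataset(labels, dn.SplitSpec(n_per_class=n_per_class, seed=split_seed))
    X_all, layout = ft.encode_features(list(labels.index))
    row = {p: i for i, p in enumerate(labels.index)}

    def subset(peps):
        idx = [row[p] for p in peps]
        return X_all[idx], (labels.loc[peps] == "unstable").to_numpy(int)

    X_tr, y_tr = subset(splits["train_fit"])
    clf = dn.train_model(X_tr, y_tr, dn.NetConfig(seed=net_seed))
    metrics_train = dn.evaluate_model(clf, X_tr, y_tr)
    X_te, y_te = subset(splits["test_4"])
    metrics_test = dn.evaluate_model(clf, X_te, y_te) if len(set(y_te)) == 2 else None

    unstable_peps = [p for p in labels.index if labels[p] == "unstable"]
    Xu, yu = subset(unstable_peps)
    correct = np.asarray(unstable_peps)[clf.predict(Xu) == 1]
    rng = np.random.default_rng(shap_seed)
    explain_peps = list(rng.choice(correct, size=min(n_explain, len(correct)), replace=False))
    Xe, _ = subset(explain_peps)
    bg_peps = rng.choice(splits["train"], size=min(n_background, len(splits["train"])), replace=False)
    Xb, _ = subset(list(bg_peps))

    explanations = si.explain_peptides(
        clf.unstable_probability, Xe, explain_peps, Xb, n_perm=n_perm, seed=shap_seed
    )
    cs = si.cluster_explanations(explanations, k="auto", k_range=k_range, seed=km_seed)
    summaries = si.summarize_and_select_motifs(cs, layout)
    motif_clusters = {c for c, s in summaries.items() if s["motif_flag"]}
    representatives = {c: si.representative_peptide(cs.members(c)) for c in range(cs.k)}

    planted = das1_rule_degrons(explain_peps, model)
    labels_planted = {p: p in planted for p in explain_peps}
    enrichment = (
        si.cluster_label_enrichment(cs, labels_planted, motif_clusters)
        if motif_clusters and len(motif_clusters) < cs.k
        else None
    )
    return {
        "library": lib,
        "psis": psis,
        "labels": labels,
        "splits": splits,
        "layout": layout,
        "classifier": clf,
        "metrics_train": metrics_train,
        "metrics_test": metrics_test,
        "explained_peptides": explain_peps,
        "explanations": explanations,
        "clusters": cs,
        "summaries": summaries,
        "motif_clusters": motif_clusters,
        "representatives": representatives,
        "planted_enrichment": enrichment,
    }


def motif_top_entries(summaries: dict[int, dict], motif_clusters: set[int]) -> set[tuple[int, str]]:
    """The (position, amino acid) of the maximal logo entry per motif cluster."""
    return {summaries[c]["top_entry"] for c in motif_clusters}
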