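"""Pipeline orchestration: run the synthetic studies, write artifacts, report.

Every artifact is written under the output directory and recorded in an
append-only manifest (path + sha256 + the config snapshot), so that a rerun
with an identical configuration reproduces identical checksums for the
deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import workflows as wf
from .psi import psi_distribution_stats, write_psi_table

log = logging.getLogger("degronmps")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "degronmps_out"
    # stage toggles
    run_recovery: bool = True
    run_motifs: bool = True
    # scale
    n_phin: int = 150
    n_w5: int = 100
    n_random: int = 350
    n_replicates: int = 3
    n_cells: int = 500_000
    reads_per_bin: int = 100_000
    motif_n_phin: int = 600
    motif_n_w5: int = 600
    motif_n_random: int = 1800
    n_per_class: int = 1000
    n_explain: int = 200
    n_perm: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


class Manifest:
    """Append-only record of written artifacts."""

    def __init__(self, out_dir: Path, config: PipelineConfig):
        self.out_dir = out_dir
        self.entries: dict[str, dict] = {}
        self.config = asdict(config)

    def add(self, name: str, path: Path) -> None:
        if name in self.entries:
            raise ValueError(f"artifact {name!r} already recorded")
        self.entries[name] = {"path": str(path.relative_to(self.out_dir)), "sha256": _sha256(path)}

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps({"config": self.config, "artifacts": self.entries}, indent=2))
        return path


def run_pipeline(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(out, cfg)
    results: dict = {}

    if cfg.run_recovery:
        log.info("recovery study: simulate -> PSI -> differential -> s/p/n -> capping")
        rec = wf.recovery_study(
            seed=cfg.seed, n_phin=cfg.n_phin, n_w5=cfg.n_w5, n_random=cfg.n_random,
            n_replicates=cfg.n_replicates, n_cells=cfg.n_cells, reads_per_bin=cfg.reads_per_bin,
        )
        results["recovery"] = rec
        p = out / "psi_wt_combined.tsv"
        write_psi_table(rec["wt_combined"], p)
        manifest.add("psi_wt_combined", p)
        p = out / "psi_das1_combined.tsv"
        write_psi_table(rec["das1_combined"], p)
        manifest.add("psi_das1_combined", p)
        p = out / "dependence_calls.tsv"
        rec["calls"].to_csv(p, sep="\t", index=False)
        manifest.add("dependence_calls", p)
        p = out / "extension_scan.tsv"
        rec["extension_scan"].grid.to_csv(p, sep="\t")
        manifest.add("extension_scan", p)

    if cfg.run_motifs:
        log.info("motif study: simulate -> label -> train -> SHAP -> cluster -> motifs")
        mot = wf.motif_discovery_study(
            seed=cfg.seed, n_phin=cfg.motif_n_phin, n_w5=cfg.motif_n_w5,
            n_random=cfg.motif_n_random, n_cells=cfg.n_cells,
            reads_per_bin=cfg.reads_per_bin, n_per_class=cfg.n_per_class,
            n_explain=cfg.n_explain, n_perm=cfg.n_perm,
        )
        results["motifs"] = mot
        mot["classifier"].save(out / "classifier")
        manifest.add("classifier_weights", out / "classifier.npz")
        manifest.add("classifier_meta", out / "classifier.json")
        expl = pd.DataFrame(
            [e.values for e in mot["explanations"]],
            index=pd.Index(mot["explained_peptides"], name="peptide"),
        )
        p = out / "shap_contributions.tsv"
        expl.to_csv(p, sep="\t")
        manifest.add("shap_contributions", p)
        for c in sorted(mot["motif_clusters"]):
            p = out / f"motif_cluster_{c}_logo.tsv"
            mot["summaries"][c]["sequence_logo"].to_csv(p, sep="\t")
            manifest.add(f"motif_cluster_{c}_logo", p)

    report = generate_report(results)
    p = out / "report.json"
    p.write_text(json.dumps(report, indent=2, default=str))
    manifest.add("report", p)
    results["manifest_path"] = manifest.write()
    results["report"] = report
    return results


def generate_report(results: dict) -> dict:
    """Human-readable summary of a pipeline run (idempotent)."""
    report: dict = {"warnings": []}
    rec = results.get("recovery")
    if rec is not None:
        from .psi import filter_psi

        wt = filter_psi(rec["wt_combined"])
        calls = rec["calls"]["call"].value_counts().to_dict()
        report["recovery"] = {
            "n_peptides": int(len(wt)),
            "n_putative_degrons_wt": int((wt["psi"] < 0.5).sum()),
            "psi_distribution": psi_distribution_stats(rec["wt_combined"]),
            "spearman_psi_truth": rec["spearman_psi_truth"],
            "dependence_calls": calls,
            "frac_planted_called_sp": rec["frac_planted_called_sp"],
            "frac_controls_called_n": rec["frac_controls_called_n"],
            "capping_is_cdegron": rec["capping"]["is_cdegron"],
            "capping_stabilizing_set": sorted(rec["capping"]["stabilizing_set"]),
        }
    else:
        report["warnings"].append("recovery stage missing; section omitted")
    mot = results.get("motifs")
    if mot is not None:
        report["motifs"] = {
            "metrics_train": mot["metrics_train"],
            "metrics_test": mot["metrics_test"],
            "n_explained": len(mot["explained_peptides"]),
            "k": mot["clusters"].k,
            "motif_clusters": sorted(mot["motif_clusters"]),
            "top_entries": {
                str(c): list(mot["summaries"][c]["top_entry"]) for c in sorted(mot["motif_clusters"])
            },
            "representatives": {str(c): mot["representatives"][c] for c in sorted(mot["motif_clusters"])},
            "planted_enrichment": mot["planted_enrichment"],
        }
    else:
        report["warnings"].append("motif stage missing; section omitted")
    return report
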