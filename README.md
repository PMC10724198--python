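# degronmps

Analysis toolkit for **multiplexed protein stability (MPS) profiling** of
C-terminal degrons — the short linear motifs that mark proteins for
ubiquitin–proteasome degradation when exposed at a protein's C-terminus.

In an MPS experiment, a library of peptides is fused to a tandem fluorescent
timer (tFT: a slow-maturing mCherry and a fast-maturing sfGFP), expressed in
yeast, FACS-sorted into stability bins by the mCherry/sfGFP ratio, and each
bin is deep-sequenced. This package covers the computational side of that
workflow end to end, driven either by real variant×bin read-count tables or
by a built-in simulator with planted degron rules:

- **Simulation** (`degronmps.synthetic`) — peptide library generation
  (random, position-constrained, proteome-like composition, saturation
  mutagenesis, +1 C-terminal extensions), per-cell fluorescence-ratio
  sampling, 8-bin sorting, multinomial sequencing, FASTQ emission.
- **Read handling** (`degronmps.amplicon`) — variable-region and bin-barcode
  extraction from merged amplicon reads, translation-level aggregation,
  count-matrix TSV IO.
- **PSI statistics** (`degronmps.psi`) — the protein stability index,
  replicate combination, per-peptide wild-type vs mutant tests with
  Benjamini–Hochberg FDR, distribution summaries, flow-cytometry fractions.
- **Degron classification** (`degronmps.classify`) — stabilized / partially
  stabilized / not affected (s/p/n) calls, mutagenesis scan matrices,
  C-degron capping analysis, colony-fluorescence screens.
- **Features & model** (`degronmps.features`, `degronmps.net`) — one-hot +
  biophysical encoding (a 12-mer → 318 features) and a small fully connected
  softmax classifier of peptide stability.
- **Interpretation** (`degronmps.interpret`) — permutation-Shapley
  attributions, k-means clustering of attribution vectors with WSS-elbow
  model selection, sequence-logo summaries, motif-cluster selection,
  Smith–Waterman representative peptides, cluster label enrichment.

## The PSI statistic

For variant *v* with reads *r*<sub>vb</sub> in bin *b*, bin read totals
*R*<sub>b</sub>, sorted-cell counts *c*<sub>b</sub> and bin fraction indices
*f*<sub>b</sub> (0 for the least stable bin, 1 for the most stable, linear
in between):

```
n_vb = (r_vb / R_b) · c_b          (estimated cells of v in bin b)
PSI_v = Σ_b n_vb · f_b / Σ_b n_vb  (cell-weighted mean bin index, in [0, 1])
```

PSI = 0 means every cell of the variant sorted into the least stable bin;
PSI = 1 the most stable. Variants with ≤ 10 total reads are flagged and
excluded by default.

## Worked example

Profile a library of 30 ΦN-terminal peptides (Φ ∈ {I,L,M,V}, asparagine at
−1 — substrates of the SCF-Das1 ubiquitin ligase) plus 70 random peptides in
wild type and a *das1* deletion, then call mutant dependence:

```python
from degronmps import (SortSimConfig, classify_dependence_table, compute_psi,
                       default_ground_truth, differential_psi, generate_library,
                       simulate_sort_seq)

model = default_ground_truth()
lib = generate_library("fixed_positions", 12, 30, fixed={-2: set("ILMV"), -1: {"N"}}, seed=0)
lib += generate_library("random", 12, 70, seed=1)

def replicates(genotype, seeds):
    tables = []
    for s in seeds:
        cfg = SortSimConfig(n_cells=200_000, reads_per_bin=50_000, seed=s)
        cm, scheme = simulate_sort_seq(lib, genotype, model, cfg)
        tables.append(compute_psi(cm, scheme))
    return tables

diff = differential_psi(replicates("wt", [10, 11, 12]), replicates("das1", [20, 21, 22]))
calls = classify_dependence_table(diff)
print(calls[["peptide", "psi_wt", "psi_mut", "delta", "padj", "call"]].head(5).round(3).to_string(index=False))
print(calls["call"].value_counts().to_string())
```

```
     peptide  psi_wt  psi_mut  delta  padj call
AAKEREPMHLYY   0.754    0.749 -0.006 0.394    n
ACITKSHFSVMN   0.085    0.680  0.595 0.000    s
AKRQEEGIDAIC   0.726    0.731  0.005 0.320    n
APTQPMMHDIQW   0.735    0.734 -0.001 0.981    n
AQMQVESALCFY   0.675    0.674 -0.000 0.984    n

call
n    65
s    35
```

`ACITKSHFSVMN` ends in MN — a ΦN degron: unstable in wild type (PSI 0.09),
restored to stability in *das1*Δ (PSI 0.68), so it is called stabilized
(`s`). The 35 `s` calls are the 30 planted ΦN peptides plus the few random
peptides that end in ΦN or carry a tryptophan at position −5, the second
planted Das1-dependent motif; peptides not recognized by Das1 stay put
(`n`). The full pipeline (classifier training, SHAP attribution, motif
clusters) runs with

```
degron-mps run-all --seed 1 --out results_dir
```

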