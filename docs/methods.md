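# Methods

This note documents the models implemented in `degronmps`, the default
parameters and the reasoning behind the open design choices.

## The measurement model

A peptide fused to a tandem fluorescent timer (tFT) reports its degradation
rate through the per-cell ratio of a slow-maturing (mCherry) to a
fast-maturing (sfGFP) fluorophore: rapidly degraded fusions are cleared
before mCherry matures, so unstable peptides give low mCherry/sfGFP ratios.
Cells are sorted into 8 bins of equal width on the ratio scale and each bin
is sequenced; the per-variant read profile across bins summarizes the
variant's stability.

### PSI

The protein stability index converts a variant's read profile into a
cell-weighted mean bin position scaled to [0, 1]. Reads are first converted
to estimated cells: the variant's read share within bin *b* multiplied by
the number of cells sorted into that bin, n_vb = (r_vb / R_b)·c_b. The
"normalized by the cell fraction count" step is implemented as this
*multiplication* — converting read share to cells — because dividing by
c_b would not produce a cell-weighted average. PSI is then Σ n_vb·f_b / Σ
n_vb with bin fraction indices f_b linearly spaced from 0 (least stable) to
1 (most stable); only the endpoints are fixed by the scale, and linear
spacing is the simplest interior choice for a weighted average over ordered
bins. Bins with zero reads contribute nothing. Variants with ≤ 10 reads
summed over bins are flagged `low_reads` and excluded from downstream
defaults.

Numerical behaviour worth knowing: PSI is invariant to multiplying all
counts within a bin by a common factor (per-bin normalization), and moving a
variant's reads to a higher bin is guaranteed not to decrease its PSI when
sequencing depth is proportional to sorted cells per bin — the pooling
scheme of the assay, where PCR products are combined proportionally to
sorted cell counts. Under strongly disproportionate depths this monotonicity
can fail, because a read move also perturbs the per-bin normalizers.

### Replicates and differential stability

Replicate PSI tables are combined by an unweighted per-peptide mean
(outer join; a peptide present in a subset of replicates is kept with its
replicate count recorded), with the sample standard error across replicates.
Wild-type vs mutant differences use an equal-variance two-sample t-test per
peptide on replicate PSIs. Because replicate counts are small, the default
`shrink` moderation replaces each peptide's pooled variance with an equal
convex combination of it and the across-peptide mean pooled variance — a
simple stand-in for moderated statistics that stabilizes near-zero replicate
variances (degrees of freedom are left at n1+n2−2). p-values are
Benjamini–Hochberg adjusted across tested peptides.

### s/p/n dependence calls

A peptide unstable in wild type (PSI < 0.5) is **s** (stabilized) in a
mutant when mutant PSI ≥ 0.58 and the PSI gain exceeds 0.1, **p**
(partially stabilized) when the gain exceeds 0.1 without reaching 0.58, and
**n** (not affected) when the gain is ≤ 0.1 or not significant. Two
interpretation choices are built in: (1) s/p additionally require
BH-adjusted p ≤ 0.05 — the printed "not affected" rule mentions p-adj,
implying significance gating for the affected calls; (2) the boundary
mutant PSI = 0.58 counts as fully stabilized so that s and p partition the
significant region and the classifier is a total function on its domain.
The C-terminome rule set additionally requires wild-type instability for an
n call; stable-in-wild-type peptides are outside that analysis and return
`unclassified`.

## The synthetic experiment

The simulator is first-class code: it defines the study conditions every
downstream stage is tested against.

**Planted rules** (the default ground truth):

| rule | matcher | effect | neutralized by |
|---|---|---|---|
| `phiN_cterm` | position −2 ∈ {I,L,M,V} and −1 = N | −0.55 | das1, cdc53, cdc34 |
| `trp_minus5` | position −5 = W | −0.45 | das1, cdc53, cdc34 |
| `hydrophobic` | linear ramp in mean Kyte–Doolittle hydropathy, 0 at −3 to 1 at +3 | up to −0.25 | doa10 |

True stability is the baseline 0.8 minus the effects of all rules not
neutralized by the genotype, clamped to [0, 1]. The ΦN and W(−5) rules are
all-or-none and strictly C-terminal; the hydrophobicity rule is graded so
that the library's true stability varies continuously (a step rule would
leave most of the library tied at the baseline, making rank-based recovery
statistics degenerate) and so that hydrophobicity correlates negatively
with PSI, as observed for real random-peptide libraries. Effects were set
so that ΦN peptides are clearly unstable in wild type (≈ 0.1–0.25) and
clearly stable in das1 (≈ 0.55–0.8), while the hydrophobic modifier stays
below the stable/unstable boundary on its own.

**Fluorescence and sorting.** Stability *s* maps linearly to a mean
log-ratio −1.25 + 2.5·s; each cell adds Gaussian noise with sd 0.3 (a
lognormal ratio). Default sorting uses 8 fixed-width bins spanning the mean
log-ratio range of stability 0–1 — the equal-width-on-the-ratio-scale scheme
of the actual assay. A quantile mode (equal cell fractions) is available,
but it is not the default because quantile bins renormalize each sort's PSI
distribution separately, destroying the cross-genotype comparability the
0.5/0.58 dependence thresholds rely on. Defaults: 5×10⁵ cells sorted and
10⁵ reads per bin; per-bin reads are drawn multinomially over variants in
proportion to the bin's realized cell tallies, mirroring
depth-proportional pooling.

**What the simulator does not model:** PCR amplification bias, sequencing
errors, paired-end merging, tFT maturation kinetics, codon-level effects,
cloning abundance skew (an optional Dirichlet skew exists but is off by
default). Passing recovery tests therefore demonstrates the statistical
machinery under idealized noise, not robustness to real library artifacts.

**FASTQ emission** writes one read per count — 5′ flank, a random
synonymous codon spelling of the peptide (uniform over codons, standard
code), 3′ flank, bin barcode — with constant Phred+33 quality, as the exact
inverse of extraction. Extraction scans for the flanks (exact match fast
path, then a Hamming scan allowing 1 mismatch by default), takes the
enclosed variable region if its length is in range, and matches the bin
barcode exactly; reads failing any step are tallied as no_flank /
bad_length / invalid_barcode.

## Features and the stability classifier

Peptides are encoded as [one-hot | per-position properties | global
properties]: 20L + 6L + 6 features (L = 12 → 318). The six property scales
are Kyte–Doolittle hydropathy, aliphatic-index coefficients (Ikai's
mole-percent formula; the per-residue coefficient scale has mean equal to
the whole-peptide formula), Zimmerman bulkiness, Deléage–Roux alpha-helix
and beta-turn propensities, and the Radzicka–Wolfenden/Boman
protein-interaction potential, bundled as `data/scales.csv`. A seventh
descriptor, mass over charge, is computed as average mass divided by
(|net charge at pH 7| + 1) — the absolute value keeps the descriptor finite
for acidic peptides, and the +1 for near-neutral ones; it can be configured
into the encoding but is not among the default six, which are the scales
with natural residue-level definitions (the published property list names
seven quantities while the feature arithmetic requires exactly six; this
is the choice made here and it is recorded in the feature-layout metadata).
Per-position features use residue-level scale values (not windowed
averages).

The classifier is a fully connected network 318 → 50 → 12 → 5 → 2-softmax:
ReLU and dropout 0.3 on each hidden layer, L1 = L2 = 0.001 penalties on the
first and last hidden layers (the published layer indexing is ambiguous;
the five-layer count reading is used), categorical cross-entropy over the
two outputs (equivalent to binary cross-entropy), Adam with default moments
and step size 0.001, batch size 500, exactly 30 epochs, no early stopping.
It is implemented directly in numpy — the network is tiny, every step is
seeded, and retraining with the same seed is bit-reproducible.
Standardization statistics come from the training split only and are stored
with the model; a provenance tag on the scaler asserts this. The validation
split (20% of the balanced training sample) is held out of fitting and used
for monitoring only. Remaining peptides are partitioned uniformly at random
into three disjoint test sets plus their union.

## SHAP attribution and motif clusters

Shapley values are estimated by permutation walks with interventional
(marginal) conditioning: per permutation one background instance is drawn,
features are switched one at a time from background to explained values in
permutation order, and each feature is credited with the induced change in
the unstable-class probability. The reverse of each permutation is also
walked (antithetic pairing), which halves the variance of ordering noise
and makes local accuracy exact: per walk the credits telescope to
f(x) − f(background), so the summed contributions equal the explained
output minus the mean background output by construction. Defaults: 100
permutations per peptide, background of 100 training instances; both
configurable. Positive contributions push toward the unstable class.

Attribution vectors (all features) are clustered with k-means, best of 5
restarts per k. The cluster count is chosen from the within-cluster
sum-of-squares curve over k = 1…8 by the maximum second difference (the
elbow); including k = 1 in the scan is required for the bend at the true
cluster count to be visible. A cluster is flagged as a potential C-degron
motif when any mean one-hot contribution at positions −5…−1 exceeds 0.05.
Each cluster is summarized by a sequence logo (mean one-hot contributions),
positional property logo, global property bars, and a representative
peptide — the member with the highest summed Smith–Waterman local-alignment
score against the rest of the cluster (BLOSUM62, gap open 10, extension
0.5, biopython convention: a gap of length k costs 10 + 0.5(k−1); ties
break lexicographically). Enrichment of externally labeled degrons inside
flagged clusters is reported as freq_in/freq_out.

## Default study scales

The end-to-end studies are sized for a workstation: the recovery study uses
a 600-peptide mixed library (150 ΦN, 100 W(−5), 350 random 12-mers), 3
replicate sorts per genotype at the default depth; the motif-discovery
study uses 3 000 peptides (600/600/1 800), a balanced training sample of
1 000 per class with PSI < 0.5 defining the unstable label, and explains
200 correctly predicted unstable peptides. These sizes recover the planted
motifs reliably across seeds while a full run stays in the minutes range.

## Known limitations

- The dispersion diagnostic d = 3.7×MAD is reported with both raw and
  1.4826-scaled MAD; no claim is made about which tail fractions a given
  reference distribution implies, as neither normalization reproduces a
  4–5% two-sided tail for a normal reference.
- The variance-shrinkage weight (0.5) is a fixed convention, not an
  empirical-Bayes estimate; with many replicates, `moderation="none"` is
  the better-calibrated choice.
- Colony-screen neighbor resolution uses a Chebyshev-radius search around
  each sample colony rather than an explicit plate-group layout; plates
  with non-adjacent controls need the radius adjusted.
- Real-data PSIs can be computed at nucleotide level and then aggregated,
  or directly at peptide level after translation-level aggregation; the
  package defaults to peptide level.
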