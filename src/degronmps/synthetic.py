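"""Synthetic tFT sort-seq experiment with planted degron rules.

Emulates the full measurement chain: a peptide library is expressed as a
tandem-fluorescent-timer (tFT) fusion, each cell's mCherry/sfGFP log-ratio
reports the fusion's stability (slow-maturing mCherry accumulates only on
long-lived protein, so a high ratio means stable), cells are FACS-sorted
into stability bins and each bin is sequenced to a fixed depth.

True stability is governed by planted, deterministic degron rules:
position-specific motifs (a C-terminal [ILMV]N dipeptide; tryptophan at
position -5) destabilize strongly and are neutralized in genotypes lacking
the recognizing ubiquitin-ligase pathway (das1, or the SCF core mutants
cdc53 / cdc34), while a graded hydrophobicity rule (Kyte-Doolittle mean)
provides the continuous, Doa10-dependent component of turnover seen for
hydrophobic peptides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .amplicon import AmpliconDesign, CountMatrix
from .peptides import AA_ALPHABET, CODONS_BY_AA, validate_peptide

GENOTYPES = ("wt", "das1", "doa10", "cdc53", "cdc34")

#: Kyte-Doolittle values inlined for rule evaluation (same table as data/scales.csv)
_KD = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4, "H": -3.2,
    "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5,
    "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}


@dataclass(frozen=True)
class DegronRule:
    """A planted destabilizing sequence rule.

    ``grade(seq)`` returns the fraction of ``stability_effect`` applied
    (0 = rule does not fire, 1 = full effect). Position rules are all-or-none;
    the hydropathy rule ramps linearly between two mean-hydropathy anchors.
    """

    name: str
    stability_effect: float
    neutralized_by: frozenset[str] = frozenset()
    # position (-L..-1, anchored at the C-terminus) -> allowed residues
    position_sets: dict[int, frozenset[str]] | None = None
    # linear ramp on mean Kyte-Doolittle hydropathy: 0 at kd_lo, 1 at kd_hi
    hydropathy_ramp: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.neutralized_by <= set(GENOTYPES):
            raise ValueError(f"neutralized_by must be within declared genotypes {GENOTYPES}")
        if (self.position_sets is None) == (self.hydropathy_ramp is None):
            raise ValueError("rule needs exactly one of position_sets / hydropathy_ramp")

    def grade(self, seq: str) -> float:
        if self.position_sets is not None:
            for pos, allowed in self.position_sets.items():
                if pos < -len(seq) or seq[pos] not in allowed:
                    return 0.0
            return 1.0
        lo, hi = self.hydropathy_ramp
        kd = sum(_KD[a] for a in seq) / len(seq)
        return float(np.clip((kd - lo) / (hi - lo), 0.0, 1.0))

    def matches(self, seq: str) -> bool:
        return self.grade(seq) > 0.0


@dataclass
class GroundTruthModel:
    """Planted rules plus the stability -> fluorescence-ratio map."""

    rules: list[DegronRule]
    baseline_stability: float = 0.8
    ratio_slope: float = 2.5
    ratio_intercept: float = -1.25
    cell_noise_sd: float = 0.3
    genotypes: tuple[str, ...] = GENOTYPES

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline_stability <= 1.0:
            raise ValueError("baseline_stability must be in [0, 1]")
        if self.cell_noise_sd < 0:
            raise ValueError("cell_noise_sd must be >= 0")

    def mean_log_ratio(self, stability) -> np.ndarray:
        return self.ratio_intercept + self.ratio_slope * np.asarray(stability, dtype=float)


def default_ground_truth() -> GroundTruthModel:
    """The study conditions used throughout the package's synthetic analyses."""
    phi = frozenset("ILMV")
    scf = frozenset({"das1", "cdc53", "cdc34"})
    rules = [
        DegronRule(
            "phiN_cterm", 0.55, neutralized_by=scf,
            position_sets={-2: phi, -1: frozenset("N")},
        ),
        DegronRule(
            "trp_minus5", 0.45, neutralized_by=scf,
            position_sets={-5: frozenset("W")},
        ),
        DegronRule(
            "hydrophobic", 0.25, neutralized_by=frozenset({"doa10"}),
            hydropathy_ramp=(-3.0, 3.0),
        ),
    ]
    return GroundTruthModel(rules)


def true_stability(seq: str, genotype: str, model: GroundTruthModel) -> float:
    """Baseline minus all non-neutralized rule effects, clamped to [0, 1]."""
    validate_peptide(seq)
    if genotype not in model.genotypes:
        raise ValueError(f"unknown genotype {genotype!r}; declared: {model.genotypes}")
    s = model.baseline_stability
    for rule in model.rules:
        if genotype in rule.neutralized_by:
            continue
        s -= rule.stability_effect * rule.grade(seq)
    return float(np.clip(s, 0.0, 1.0))


# -- library generation -------------------------------------------------------

#: Approximate amino-acid frequencies of the yeast proteome, used for
#: "cterminome_like" libraries (natural composition rather than uniform).
_YEAST_AA_FREQ = {
    "A": 0.055, "C": 0.013, "D": 0.058, "E": 0.065, "F": 0.045, "G": 0.050,
    "H": 0.022, "I": 0.065, "K": 0.073, "L": 0.096, "M": 0.021, "N": 0.061,
    "P": 0.044, "Q": 0.039, "R": 0.044, "S": 0.090, "T": 0.059, "V": 0.056,
    "W": 0.010, "Y": 0.034,
}


def _normalize_fixed(fixed, length):
    out = {}
    for pos, allowed in (fixed or {}).items():
        if not -length <= pos <= -1:
            raise ValueError(f"fixed position {pos} outside -{length}..-1")
        allowed = sorted(set(allowed))
        if not allowed or not set(allowed) <= set(AA_ALPHABET):
            raise ValueError(f"invalid amino-acid set for position {pos}")
        out[length + pos] = allowed  # 0-based index
    return out


def generate_library(
    kind: str,
    length: int,
    n_variants: int,
    fixed: dict[int, set[str]] | None = None,
    seed: int = 0,
) -> list[str]:
    """Generate ``n_variants`` unique peptides of ``length``.

    kinds: ``random`` (i.i.d. uniform residues), ``fixed_positions`` (uniform
    except the ``fixed`` position -> allowed-set constraints, positions given
    C-terminus-anchored), ``cterminome_like`` (residues drawn from natural
    yeast amino-acid frequencies).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if kind not in ("random", "fixed_positions", "cterminome_like"):
        raise ValueError(f"unknown library kind {kind!r}")
    fixed_idx = _normalize_fixed(fixed if kind == "fixed_positions" else None, length)
    # capacity check
    n_possible = 1.0
    for i in range(length):
        n_possible *= len(fixed_idx.get(i, AA_ALPHABET))
        if n_possible >= 1e18:
            break
    if n_variants > n_possible:
        raise ValueError(
            f"requested {n_variants} variants but only {int(n_possible)} "
            f"sequences of length {length} satisfy the constraints"
        )
    rng = np.random.default_rng(seed)
    if kind == "cterminome_like":
        probs = np.array([_YEAST_AA_FREQ[a] for a in AA_ALPHABET])
        probs = probs / probs.sum()
    else:
        probs = None
    alphabet = np.array(list(AA_ALPHABET))
    seen: dict[str, None] = {}
    while len(seen) < n_variants:
        n_draw = max(64, 2 * (n_variants - len(seen)))
        block = alphabet[rng.choice(20, size=(n_draw, length), p=probs)]
        for i, choices in fixed_idx.items():
            block[:, i] = np.array(choices)[rng.integers(0, len(choices), size=n_draw)]
        for row in block:
            seq = "".join(row)
            if seq not in seen:
                seen[seq] = None
                if len(seen) == n_variants:
                    break
    return list(seen)


def build_mutant_libraries(wt: str) -> dict[str, list[str]]:
    """All single-substitution mutants and all +1 C-terminal extensions of ``wt``.

    ``saturation`` holds the 19L+1 unique sequences (wild type first);
    ``extension`` holds wt followed by wt+a for each of the 20 amino acids.
    """
    validate_peptide(wt)
    saturation = [wt]
    seen = {wt}
    for i in range(len(wt)):
        for a in AA_ALPHABET:
            m = wt[:i] + a + wt[i + 1 :]
            if m not in seen:
                seen.add(m)
                saturation.append(m)
    extension = [wt] + [wt + a for a in AA_ALPHABET]
    return {"saturation": saturation, "extension": extension}


# -- sort-seq simulation ------------------------------------------------------


@dataclass
class SortSimConfig:
    """Scale and binning of one simulated sort-seq run."""

    n_bins: int = 8
    n_cells: int = 500_000
    reads_per_bin: int = 100_000
    bin_mode: str = "fixed"  # "fixed" width on log-ratio scale, or "quantile"
    bin_boundaries: np.ndarray | None = None  # n_bins-1 increasing log-ratio cuts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.n_cells < 1 or self.reads_per_bin < 1:
            raise ValueError("n_cells and reads_per_bin must be positive")
        if self.bin_mode not in ("fixed", "quantile"):
            raise ValueError(f"unknown bin_mode {self.bin_mode!r}")
        if self.bin_boundaries is not None:
            b = np.asarray(self.bin_boundaries, dtype=float)
            if b.shape != (self.n_bins - 1,) or not np.all(np.diff(b) > 0):
                raise ValueError("bin_boundaries must be n_bins-1 strictly increasing values")
            self.bin_boundaries = b


def _boundaries(cfg: SortSimConfig, model: GroundTruthModel, log_ratios: np.ndarray) -> np.ndarray:
    if cfg.bin_boundaries is not None:
        return cfg.bin_boundaries
    if cfg.bin_mode == "quantile":
        qs = np.linspace(0, 1, cfg.n_bins + 1)[1:-1]
        return np.quantile(log_ratios, qs)
    # fixed width across the mean-ratio range of stability 0..1
    lo = model.ratio_intercept
    hi = model.ratio_intercept + model.ratio_slope
    return np.linspace(lo, hi, cfg.n_bins + 1)[1:-1]


def simulate_sort_seq(
    lib: list[str],
    genotype: str,
    model: GroundTruthModel,
    cfg: SortSimConfig,
    abundances: np.ndarray | None = None,
    return_cells: bool = False,
):
    """Simulate sorting + sequencing of ``lib`` in ``genotype``.

    Each cell expresses one variant (uniform by default, or ``abundances``),
    draws a log fluorescence ratio Normal(intercept + slope*stability, sd),
    and is assigned to a bin; each non-empty bin is then sequenced to
    ``reads_per_bin`` reads, multinomially over variants in proportion to the
    bin's cell tallies.

    Returns ``(CountMatrix, BinScheme)`` (plus a per-cell DataFrame when
    ``return_cells``). The CountMatrix also carries the realized per-bin cell
    counts.
    """
    from .psi import BinScheme  # local import to avoid a cycle

    if not lib:
        raise ValueError("library is empty")
    rng = np.random.default_rng(cfg.seed)
    n_var = len(lib)
    stab = np.array([true_stability(p, genotype, model) for p in lib])
    if abundances is not None:
        abundances = np.asarray(abundances, dtype=float)
        abundances = abundances / abundances.sum()
    variant_idx = rng.choice(n_var, size=cfg.n_cells, p=abundances)
    log_ratio = model.mean_log_ratio(stab)[variant_idx]
    if model.cell_noise_sd > 0:
        log_ratio = log_ratio + rng.normal(0.0, model.cell_noise_sd, size=cfg.n_cells)
    cuts = _boundaries(cfg, model, log_ratio)
    bin_idx = np.searchsorted(cuts, log_ratio, side="right")

    cells_vb = np.zeros((n_var, cfg.n_bins), dtype=np.int64)
    np.add.at(cells_vb, (variant_idx, bin_idx), 1)
    cells_b = cells_vb.sum(axis=0)

    reads = np.zeros((n_var, cfg.n_bins), dtype=np.int64)
    for b in range(cfg.n_bins):
        if cells_b[b] == 0:
            continue
        reads[:, b] = rng.multinomial(cfg.reads_per_bin, cells_vb[:, b] / cells_b[b])

    cm = CountMatrix(list(lib), reads, level="peptide", cell_counts=cells_b.astype(float))
    scheme = BinScheme(n_bins=cfg.n_bins, cell_counts=cells_b.astype(float))
    if return_cells:
        cells = pd.DataFrame(
            {"variant": [lib[i] for i in variant_idx], "log_ratio": log_ratio, "bin": bin_idx + 1}
        )
        return cm, scheme, cells
    return cm, scheme


def ground_truth_table(lib: list[str], model: GroundTruthModel, genotypes=GENOTYPES) -> pd.DataFrame:
    """Tidy (peptide, genotype, true_stability) table for test harnesses."""
    rows = [
        {"peptide": p, "genotype": g, "true_stability": true_stability(p, g, model)}
        for p in lib
        for g in genotypes
    ]
    return pd.DataFrame(rows)


# -- FASTQ emission (inverse of extraction) ----------------------------------


def default_amplicon_design(n_bins: int = 8) -> AmpliconDesign:
    """A compact synthetic amplicon design with one barcode per bin."""
    barcodes = [
        "AACCGG", "TTGGCC", "ACACGT", "TGTGCA",
        "AAGGTT", "TTCCAA", "AGAGCT", "TCTCGA",
        "ACGTAC", "TGCATG", "AATTGG", "TTAACC",
    ][:n_bins]
    if len(barcodes) < n_bins:
        raise ValueError("no default barcodes for more than 12 bins")
    return AmpliconDesign(
        flank5="ACGGATCCGGTGGATCG",
        flank3="TGATAAGCGGCCGCTAA",
        bin_barcodes=barcodes,
        variable_length_range=(3, 60),
        max_flank_mismatches=1,
    )


def emit_amplicon_fastq(cm: CountMatrix, design: AmpliconDesign, seed: int, handle) -> int:
    """Write one FASTQ record per read in ``cm`` (inverse of extract_and_count).

    Peptide-level variants are reverse-translated with random synonymous
    codons per read (seeded); nucleotide-level variants are written as-is.
    Returns the number of records written.
    """
    if cm.n_bins > design.n_bins:
        raise ValueError("CountMatrix has more bins than design barcodes")
    rng = np.random.default_rng(seed)
    n_written = 0
    for v, row in zip(cm.variants, cm.counts):
        for b in range(cm.n_bins):
            n = int(row[b])
            for _ in range(n):
                if cm.level == "peptide":
                    cds = "".join(
                        CODONS_BY_AA[a][rng.integers(0, len(CODONS_BY_AA[a]))] for a in v
                    )
                else:
                    cds = v
                seq = design.flank5 + cds + design.flank3 + design.bin_barcodes[b]
                handle.write(f"@read{n_written}\n{seq}\n+\n{'I' * len(seq)}\n")
                n_written += 1
    return n_written
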