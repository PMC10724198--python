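"""Peptide primitives shared across the package.

Peptides are plain strings over the 20-letter amino-acid alphabet. Positions
are indexed from the C-terminus: -1 is the C-terminal residue, -L the most
N-terminal residue of an L-mer (the residue closest to the fluorescent-timer
fusion). A "+1" position denotes a single residue appended after -1.
"""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

#: Fixed one-letter alphabet, alphabetical order; used for all grids/one-hots.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ALPHABET)
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

#: amino acid -> list of synonymous codons (standard nuclear code)
CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _aa in CODONS_BY_AA:
    CODONS_BY_AA[_aa].sort()


def validate_peptide(seq: str) -> str:
    """Check ``seq`` is a non-empty string over the amino-acid alphabet."""
    if not isinstance(seq, str) or len(seq) == 0:
        raise ValueError("peptide must be a non-empty string")
    bad = set(seq) - AA_SET
    if bad:
        raise ValueError(f"invalid amino-acid characters {sorted(bad)!r} in {seq!r}")
    return seq


def residue_at(seq: str, position: int) -> str:
    """Residue at C-terminal-anchored ``position`` (-1 = C-terminus)."""
    if position >= 0 or position < -len(seq):
        raise IndexError(f"position {position} outside -{len(seq)}..-1")
    return seq[position]


def translate_nt(nt: str) -> str:
    """Translate an in-frame nucleotide string (standard code)."""
    if len(nt) % 3 != 0:
        raise ValueError(f"length of {nt!r} not divisible by 3")
    return str(Seq(nt).translate())
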