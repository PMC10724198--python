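"""Amplicon read extraction and count-matrix IO.

Merged amplicon reads have the layout

    [phased random nt] flank5 [variable region] flank3 [bin barcode] ...

The variable region between the two design-specific flanking sequences is the
peptide-coding sequence; the barcode after the 3' flank identifies the
stability bin the read came from. Reads whose flanks cannot be located,
whose variable region has an unexpected length, or whose barcode is not in
the design are discarded and tallied by reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

from .peptides import translate_nt

DISCARD_REASONS = ("low_quality", "no_flank", "bad_length", "invalid_barcode")


@dataclass
class AmpliconDesign:
    """Declared structure of the sequenced amplicon."""

    flank5: str
    flank3: str
    bin_barcodes: list[str]
    variable_length_range: tuple[int, int]
    max_flank_mismatches: int = 1

    def __post_init__(self) -> None:
        if not self.flank5 or not self.flank3:
            raise ValueError("flanking sequences must be non-empty")
        if len(set(self.bin_barcodes)) != len(self.bin_barcodes):
            raise ValueError("bin barcodes must be unique")
        if len({len(b) for b in self.bin_barcodes}) != 1:
            raise ValueError("bin barcodes must have equal length")
        lo, hi = self.variable_length_range
        if lo > hi or lo < 1:
            raise ValueError("invalid variable_length_range")
        if self.max_flank_mismatches < 0:
            raise ValueError("max_flank_mismatches must be >= 0")

    @property
    def n_bins(self) -> int:
        return len(self.bin_barcodes)

    @property
    def barcode_length(self) -> int:
        return len(self.bin_barcodes[0])


@dataclass
class CountMatrix:
    """variants x bins non-negative read counts, bins ordered least->most stable.

    ``cell_counts`` optionally carries the number of cells sorted into each
    bin (needed to turn read shares back into cell-weighted averages).
    """

    variants: list[str]
    counts: np.ndarray  # (n_variants, n_bins) integers
    level: str = "nucleotide"  # or "peptide"
    cell_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != len(self.variants):
            raise ValueError("counts must be (n_variants, n_bins)")
        if (self.counts < 0).any():
            raise ValueError("negative read counts")
        if len(set(self.variants)) != len(self.variants):
            raise ValueError("duplicate variant identifiers")
        if self.level not in ("nucleotide", "peptide"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.cell_counts is not None:
            self.cell_counts = np.asarray(self.cell_counts, dtype=float)
            if self.cell_counts.shape != (self.n_bins,):
                raise ValueError("cell_counts length must equal number of bins")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.variants, name="variant"),
            columns=[f"bin_{b + 1}" for b in range(self.n_bins)],
        )


def _hamming_find(haystack: str, needle: str, max_mismatches: int, start: int = 0, stop: int | None = None) -> int:
    """Leftmost start index where ``needle`` matches with <= max_mismatches, else -1."""
    exact = haystack.find(needle, start, (stop + len(needle)) if stop is not None else None)
    if exact != -1 or max_mismatches == 0:
        return exact
    n = len(needle)
    last = (len(haystack) - n) if stop is None else min(stop, len(haystack) - n)
    for i in range(start, last + 1):
        window = haystack[i : i + n]
        mism = 0
        for a, b in zip(window, needle):
            if a != b:
                mism += 1
                if mism > max_mismatches:
                    break
        else:
            return i
    return -1


def _iter_fastq(source: str | Path | IO[str] | Iterable) -> Iterator:
    if isinstance(source, (str, Path)):
        yield from SeqIO.parse(str(source), "fastq")
    elif hasattr(source, "read"):
        yield from SeqIO.parse(source, "fastq")
    else:  # already records
        yield from source


def extract_and_count(
    reads, design: AmpliconDesign, min_mean_quality: float | None = None
) -> tuple[CountMatrix, dict[str, int]]:
    """Extract variable regions + bin barcodes from merged reads and count them.

    Returns a nucleotide-level :class:`CountMatrix` and a discard report
    ``{reason: n_reads}`` with ``reads_in`` and ``counted`` totals included.
    ``min_mean_quality`` optionally discards reads whose mean Phred quality
    falls below the threshold (off by default).
    """
    lo, hi = design.variable_length_range
    bc_len = design.barcode_length
    bc_to_bin = {bc: b for b, bc in enumerate(design.bin_barcodes)}
    tallies: dict[tuple[str, int], int] = {}
    report = {r: 0 for r in DISCARD_REASONS}
    n_reads = 0
    record_iter = _iter_fastq(reads)
    index = 0
    while True:
        try:
            record = next(record_iter)
        except StopIteration:
            break
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record at index {index}: {exc}") from exc
        index += 1
        n_reads += 1
        if min_mean_quality is not None:
            quals = record.letter_annotations.get("phred_quality", [])
            if quals and float(np.mean(quals)) < min_mean_quality:
                report["low_quality"] += 1
                continue
        seq = str(record.seq).upper()
        i5 = _hamming_find(seq, design.flank5, design.max_flank_mismatches)
        if i5 == -1:
            report["no_flank"] += 1
            continue
        var_start = i5 + len(design.flank5)
        i3 = _hamming_find(
            seq, design.flank3, design.max_flank_mismatches,
            start=var_start + lo, stop=var_start + hi,
        )
        if i3 == -1:
            # flank3 may sit closer than lo if the region is short: classify
            anywhere = _hamming_find(seq, design.flank3, design.max_flank_mismatches, start=var_start)
            report["bad_length" if anywhere != -1 else "no_flank"] += 1
            continue
        variable = seq[var_start:i3]
        if not lo <= len(variable) <= hi:
            report["bad_length"] += 1
            continue
        bc = seq[i3 + len(design.flank3) : i3 + len(design.flank3) + bc_len]
        if bc not in bc_to_bin:
            report["invalid_barcode"] += 1
            continue
        key = (variable, bc_to_bin[bc])
        tallies[key] = tallies.get(key, 0) + 1

    variants = sorted({v for v, _ in tallies})
    counts = np.zeros((len(variants), design.n_bins), dtype=np.int64)
    v_index = {v: i for i, v in enumerate(variants)}
    for (v, b), n in tallies.items():
        counts[v_index[v], b] = n
    report["reads_in"] = n_reads
    report["counted"] = int(counts.sum())
    return CountMatrix(variants, counts, level="nucleotide"), report


def translate_and_aggregate(
    cm: CountMatrix, stop_policy: str = "drop"
) -> tuple[CountMatrix, dict]:
    """Sum synonymous nucleotide variants into peptide-level counts.

    Variants containing an in-frame stop are dropped (``stop_policy='drop'``)
    or raise (``'error'``); dropped variants and reads are reported.
    """
    if cm.level != "nucleotide":
        raise ValueError("input must be a nucleotide-level CountMatrix")
    bad_len = [v for v in cm.variants if len(v) % 3 != 0]
    if bad_len:
        raise ValueError(f"variant lengths not divisible by 3: {bad_len[:5]}")
    agg: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    dropped_reads = 0
    for v, row in zip(cm.variants, cm.counts):
        pep = translate_nt(v)
        if "*" in pep:
            if stop_policy == "error":
                raise ValueError(f"in-frame stop codon in variant {v!r}")
            dropped.append(v)
            dropped_reads += int(row.sum())
            continue
        if pep in agg:
            agg[pep] = agg[pep] + row
        else:
            agg[pep] = row.copy()
    peptides = sorted(agg)
    counts = (
        np.stack([agg[p] for p in peptides])
        if peptides
        else np.zeros((0, cm.n_bins), dtype=np.int64)
    )
    out = CountMatrix(peptides, counts, level="peptide", cell_counts=cm.cell_counts)
    return out, {"dropped_variants": dropped, "dropped_reads": dropped_reads}


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if cm.cell_counts is not None:
            fh.write("#cells:\t" + "\t".join(repr(float(c)) for c in cm.cell_counts) + "\n")
        fh.write("#level:\t" + cm.level + "\n")
        header = ["variant"] + [f"bin_{b + 1}" for b in range(cm.n_bins)]
        fh.write("\t".join(header) + "\n")
        for v, row in zip(cm.variants, cm.counts):
            fh.write(v + "\t" + "\t".join(str(int(x)) for x in row) + "\n")


def read_count_matrix(path: str | Path) -> CountMatrix:
    path = Path(path)
    cell_counts = None
    level = "nucleotide"
    with path.open() as fh:
        line = fh.readline()
        while line.startswith("#"):
            key, _, rest = line.rstrip("\n").partition("\t")
            if key == "#cells:":
                cell_counts = np.array([float(x) for x in rest.split("\t")])
            elif key == "#level:":
                level = rest.strip()
            line = fh.readline()
        header = line.rstrip("\n").split("\t")
        if not header or header[0] != "variant":
            raise ValueError("count matrix must have a 'variant' first column")
        n_bins = len(header) - 1
        if n_bins < 1:
            raise ValueError("count matrix is missing bin columns")
        variants, rows = [], []
        for ln in fh:
            if not ln.strip():
                continue
            parts = ln.rstrip("\n").split("\t")
            if len(parts) != n_bins + 1:
                raise ValueError(f"row {parts[0]!r} has {len(parts) - 1} bins, expected {n_bins}")
            variants.append(parts[0])
            rows.append([int(x) for x in parts[1:]])
    counts = np.array(rows, dtype=np.int64).reshape(len(variants), n_bins)
    if (counts < 0).any():
        raise ValueError("negative count in file")
    return CountMatrix(variants, counts, level=level, cell_counts=cell_counts)


def write_discard_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
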