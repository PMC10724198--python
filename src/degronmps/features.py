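"""Peptide biophysical descriptors, classifier feature encoding and
library-level sequence/stability statistics.

Six residue-level property scales (bundled under ``data/scales.csv`` with
literature provenance: Kyte-Doolittle hydropathy, Ikai aliphatic-index
coefficients, Zimmerman bulkiness, Deleage-Roux alpha-helix and beta-turn
propensities, Radzicka-Wolfenden/Boman protein-interaction potential) drive
both per-position features and whole-peptide aggregates. A peptide of length
L encodes to 20L one-hot + 6L per-position + 6 global = 26L + 6 features
(L = 12 -> 318).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .peptides import AA_ALPHABET, AA_INDEX, validate_peptide

MEAN_SCALES = (
    "hydropathy_KD",
    "bulkiness",
    "alpha_propensity",
    "turn_propensity",
    "interaction_index",
)
PROPERTY_SCALES = MEAN_SCALES + ("aliphatic_index", "mass_over_charge")
#: the six properties used in the classifier encoding (per-position + global)
DEFAULT_SIX = (
    "hydropathy_KD",
    "aliphatic_index",
    "bulkiness",
    "alpha_propensity",
    "turn_propensity",
    "interaction_index",
)

_SCALE_COLUMN = {
    "hydropathy_KD": "hydropathy_kd",
    "bulkiness": "bulkiness",
    "alpha_propensity": "alpha_propensity",
    "turn_propensity": "turn_propensity",
    "interaction_index": "interaction_index",
    "aliphatic_index": "aliphatic_coef",
}

#: side-chain / terminal pKa values (EMBOSS set) for net charge at pH 7
_PKA = {"Nterm": 8.6, "Cterm": 3.6, "K": 10.8, "R": 12.5, "H": 6.5, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}
_WATER_MASS = 18.01524


def _load_scales() -> pd.DataFrame:
    with resources.files("degronmps.data").joinpath("scales.csv").open() as fh:
        return pd.read_csv(fh, index_col="aa")


_SCALES = _load_scales()


def residue_values(scale: str) -> np.ndarray:
    """Per-residue values of ``scale`` in alphabet order.

    For the aliphatic index the residue value is its mole-percent
    coefficient (100 A, 290 V, 390 I/L, 0 otherwise), whose mean over the
    peptide equals the Ikai formula.
    """
    if scale not in _SCALE_COLUMN:
        raise ValueError(f"no per-residue table for scale {scale!r}")
    col = _SCALES[_SCALE_COLUMN[scale]]
    return np.array([col[a] for a in AA_ALPHABET], dtype=float)


def net_charge(seq: str, ph: float = 7.0) -> float:
    """Henderson-Hasselbalch net charge including free termini."""

    def pos(pka):
        return 1.0 / (1.0 + 10 ** (ph - pka))

    def neg(pka):
        return -1.0 / (1.0 + 10 ** (pka - ph))

    q = pos(_PKA["Nterm"]) + neg(_PKA["Cterm"])
    for a in seq:
        if a in ("K", "R", "H"):
            q += pos(_PKA[a])
        elif a in ("D", "E", "C", "Y"):
            q += neg(_PKA[a])
    return q


def peptide_mass(seq: str) -> float:
    return float(sum(_SCALES["residue_mass"][a] for a in seq) + _WATER_MASS)


def compute_property(seq: str, scale: str) -> float:
    """Whole-peptide value of one of the seven supported property scales.

    Mean scales average per-residue values; the aliphatic index uses the
    mole-percent formula X_A + 2.9 X_V + 3.9 (X_I + X_L); mass_over_charge
    is the average mass divided by (|net charge at pH 7| + 1), the +1
    keeping the descriptor finite near neutrality.
    """
    validate_peptide(seq)
    if scale in MEAN_SCALES or scale == "aliphatic_index":
        vals = residue_values(scale)
        return float(np.mean([vals[AA_INDEX[a]] for a in seq]))
    if scale == "mass_over_charge":
        return peptide_mass(seq) / (abs(net_charge(seq)) + 1.0)
    raise ValueError(f"unknown property scale {scale!r}")


@dataclass
class FeatureLayout:
    """Block layout of the encoded feature vector."""

    length: int
    scales: tuple[str, ...] = DEFAULT_SIX

    @property
    def n_onehot(self) -> int:
        return 20 * self.length

    @property
    def n_positional(self) -> int:
        return len(self.scales) * self.length

    @property
    def n_features(self) -> int:
        return self.n_onehot + self.n_positional + len(self.scales)

    def onehot_slice(self) -> slice:
        return slice(0, self.n_onehot)

    def positional_slice(self) -> slice:
        return slice(self.n_onehot, self.n_onehot + self.n_positional)

    def global_slice(self) -> slice:
        return slice(self.n_onehot + self.n_positional, self.n_features)

    def positions(self) -> list[int]:
        return list(range(-self.length, 0))

    def to_dict(self) -> dict:
        return {
            "length": self.length,
            "scales": list(self.scales),
            "n_features": self.n_features,
            "blocks": {
                "onehot": [0, self.n_onehot],
                "positional": [self.n_onehot, self.n_onehot + self.n_positional],
                "global": [self.n_onehot + self.n_positional, self.n_features],
            },
        }


def encode_features(
    peptides: list[str] | str, layout: FeatureLayout | None = None
) -> tuple[np.ndarray, FeatureLayout]:
    """Encode peptide(s) into [one-hot | per-position properties | global] rows.

    One-hot block is position-major over positions -L..-1 x alphabet order;
    positional block is scale-major (for each scale, L residue-level values);
    global block holds the whole-peptide property values. All peptides in one
    call must share a length.
    """
    if isinstance(peptides, str):
        peptides = [peptides]
    if not peptides:
        raise ValueError("no peptides to encode")
    L = len(peptides[0])
    if layout is None:
        layout = FeatureLayout(length=L)
    if layout.length != L:
        raise ValueError("layout length differs from peptide length")
    per_res = {s: residue_values(s) for s in layout.scales if s != "mass_over_charge"}
    X = np.zeros((len(peptides), layout.n_features))
    for r, seq in enumerate(peptides):
        validate_peptide(seq)
        if len(seq) != L:
            raise ValueError("mixed peptide lengths in one dataset")
        idx = np.array([AA_INDEX[a] for a in seq])
        X[r, np.arange(L) * 20 + idx] = 1.0
        off = layout.n_onehot
        for s in layout.scales:
            if s == "mass_over_charge":
                X[r, off : off + L] = 0.0  # no residue-level definition
            else:
                X[r, off : off + L] = per_res[s][idx]
            off += L
        X[r, layout.global_slice()] = [compute_property(seq, s) for s in layout.scales]
    return X, layout


# -- library-level statistics -------------------------------------------------


def _position_freqs(peps: list[str], L: int) -> np.ndarray:
    freq = np.zeros((L, 20))
    for seq in peps:
        for i, a in enumerate(seq):
            freq[i, AA_INDEX[a]] += 1
    return freq / len(peps)


def positional_enrichment(
    target: list[str], background: list[str], unit: str = "amino_acid"
) -> pd.DataFrame:
    """log2 relative frequency of residues (or C-terminal dipeptides) in
    ``target`` versus ``background``.

    Returns a tidy table (position, unit, log2_ratio, flag); entries absent
    from the target are flagged ``absent``, entries with zero background but
    nonzero target frequency are flagged ``undefined`` — neither carries an
    infinite value.
    """
    if not target or not background:
        raise ValueError("target and background must be non-empty")
    L = len(background[0])
    if any(len(p) != L for p in target) or any(len(p) != L for p in background):
        raise ValueError("all peptides must share one length")
    rows = []
    if unit == "amino_acid":
        ft = _position_freqs(target, L)
        fb = _position_freqs(background, L)
        for i in range(L):
            pos = i - L
            for j, a in enumerate(AA_ALPHABET):
                t, b = ft[i, j], fb[i, j]
                if t == 0:
                    rows.append({"position": pos, "unit": a, "log2_ratio": np.nan, "flag": "absent"})
                elif b == 0:
                    rows.append({"position": pos, "unit": a, "log2_ratio": np.nan, "flag": "undefined"})
                else:
                    rows.append({"position": pos, "unit": a, "log2_ratio": np.log2(t / b), "flag": ""})
    elif unit == "cterm_dipeptide":
        def dip_freq(peps):
            c: dict[str, float] = {}
            for p in peps:
                d = p[-2:]
                c[d] = c.get(d, 0) + 1
            return {d: n / len(peps) for d, n in c.items()}

        ft, fb = dip_freq(target), dip_freq(background)
        for a in AA_ALPHABET:
            for b_ in AA_ALPHABET:
                d = a + b_
                t, b = ft.get(d, 0.0), fb.get(d, 0.0)
                if t == 0:
                    rows.append({"position": -2, "unit": d, "log2_ratio": np.nan, "flag": "absent"})
                elif b == 0:
                    rows.append({"position": -2, "unit": d, "log2_ratio": np.nan, "flag": "undefined"})
                else:
                    rows.append({"position": -2, "unit": d, "log2_ratio": np.log2(t / b), "flag": ""})
    else:
        raise ValueError(f"unknown unit {unit!r}")
    return pd.DataFrame(rows)


def psi_sequence_associations(psis: pd.DataFrame) -> dict:
    """Dipeptide position effects and the hydrophobicity-PSI correlation.

    For every dipeptide d, Delta(d) = mean PSI of peptides carrying d at the
    C-terminus (-2,-1) minus mean PSI of peptides carrying d internally
    (both residues within -L..-3); a peptide may contribute to both groups.
    Also returns Spearman rho between mean Kyte-Doolittle hydropathy and PSI.
    """
    t = psis[psis["flags"] == ""]
    peps = t["peptide"].tolist()
    vals = t["psi"].to_numpy()
    if not peps:
        raise ValueError("no usable peptides")
    if min(len(p) for p in peps) < 4:
        raise ValueError("peptides must be length >= 4 for the internal/terminal split")
    term: dict[str, list[float]] = {}
    intern: dict[str, list[float]] = {}
    for seq, v in zip(peps, vals):
        term.setdefault(seq[-2:], []).append(v)
        inner = seq[:-2]
        seen = set()
        for i in range(len(inner) - 1):
            d = inner[i : i + 2]
            if d not in seen:
                intern.setdefault(d, []).append(v)
                seen.add(d)
    rows = []
    for a in AA_ALPHABET:
        for b in AA_ALPHABET:
            d = a + b
            tv, iv = term.get(d), intern.get(d)
            if tv and iv:
                rows.append(
                    {"dipeptide": d, "delta_mean_psi": float(np.mean(tv) - np.mean(iv)),
                     "n_terminal": len(tv), "n_internal": len(iv), "flag": ""}
                )
            else:
                rows.append(
                    {"dipeptide": d, "delta_mean_psi": np.nan,
                     "n_terminal": len(tv or []), "n_internal": len(iv or []), "flag": "empty_group"}
                )
    kd = np.array([compute_property(p, "hydropathy_KD") for p in peps])
    rho = spearmanr(kd, vals).statistic if len(peps) > 2 else np.nan
    return {"dipeptide_table": pd.DataFrame(rows), "spearman_rho_hydropathy": float(rho)}
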