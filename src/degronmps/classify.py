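"""Mutant-dependence classification, mutagenesis scans and colony screens.

The stabilized / partially stabilized / not affected (s/p/n) calls transcribe
the published threshold rules: a peptide unstable in the wild type
(PSI < 0.5) is *stabilized* in a mutant when its mutant PSI exceeds 0.58 and
increases by more than 0.1, *partially stabilized* when the increase exceeds
0.1 without crossing 0.58, and *not affected* otherwise. Significant calls
(s/p) additionally require BH-adjusted p <= alpha; a non-significant increase
above 0.1 is "not affected".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isnan

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .peptides import AA_ALPHABET, validate_peptide
from .synthetic import build_mutant_libraries


@dataclass(frozen=True)
class DependenceThresholds:
    unstable: float = 0.5       # wt PSI below this = unstable in wild type
    stable_mut: float = 0.58    # mutant PSI at/above this = fully stabilized
    min_delta: float = 0.1      # PSI gain required to call an effect
    alpha: float = 0.05         # BH-adjusted significance for s/p calls


def classify_dependence(
    wt_psi: float,
    mut_psi: float,
    padj: float | None,
    ruleset: str = "degron_library",
    thresholds: DependenceThresholds = DependenceThresholds(),
) -> str:
    """One of 's', 'p', 'n' or 'unclassified' for a wt/mutant PSI pair.

    ``ruleset='cterminome'`` additionally requires wt PSI < 0.5 for an 'n'
    call (stable-in-wt peptides are outside that analysis and come back
    'unclassified'). A missing PSI always yields 'unclassified'. The
    boundary mut_psi == stable_mut counts as fully stabilized so that s/p
    partition the significant region.
    """
    if ruleset not in ("degron_library", "cterminome"):
        raise ValueError(f"unknown ruleset {ruleset!r}")
    t = thresholds
    if wt_psi is None or mut_psi is None or isnan(wt_psi) or isnan(mut_psi):
        return "unclassified"
    delta = mut_psi - wt_psi
    padj_missing = padj is None or (isinstance(padj, float) and isnan(padj))
    significant = (not padj_missing) and padj <= t.alpha
    if wt_psi < t.unstable and delta > t.min_delta and significant:
        return "s" if mut_psi >= t.stable_mut else "p"
    not_affected = (delta > t.min_delta and not significant) or delta <= t.min_delta
    if ruleset == "cterminome" and not wt_psi < t.unstable:
        return "unclassified"
    if not_affected:
        return "n"
    return "unclassified"


def classify_dependence_table(
    diff: pd.DataFrame,
    ruleset: str = "degron_library",
    thresholds: DependenceThresholds = DependenceThresholds(),
) -> pd.DataFrame:
    """Apply :func:`classify_dependence` to a differential-PSI table."""
    calls = [
        classify_dependence(r.psi_wt, r.psi_mut, r.padj, ruleset, thresholds)
        for r in diff.itertuples()
    ]
    out = diff.copy()
    out["call"] = calls
    return out


# -- mutagenesis scan matrices ------------------------------------------------


@dataclass
class ScanMatrix:
    """PSI grid over single mutants of a wild-type peptide.

    ``saturation``: rows = 20 amino acids (alphabetical), columns = positions
    -L..-1; ``extension``: a single row indexed '-' (no extension) then the
    20 amino acids appended at +1. Missing library members are NaN with
    ``missing`` True, never zero.
    """

    kind: str
    wt: str
    grid: pd.DataFrame
    missing: pd.DataFrame


def build_scan_matrix(psis: pd.DataFrame, wt: str, kind: str) -> ScanMatrix:
    validate_peptide(wt)
    if kind not in ("saturation", "extension"):
        raise ValueError(f"unknown scan kind {kind!r}")
    lookup = psis.set_index("peptide")["psi"]
    if wt not in lookup.index or isnan(lookup[wt]):
        raise ValueError(f"wild-type peptide {wt!r} absent from PSI table")
    L = len(wt)
    if kind == "saturation":
        cols = list(range(-L, 0))
        grid = pd.DataFrame(np.nan, index=list(AA_ALPHABET), columns=cols)
        for pos in cols:
            i = L + pos
            for a in AA_ALPHABET:
                m = wt[:i] + a + wt[i + 1 :]
                if m in lookup.index:
                    grid.loc[a, pos] = lookup[m]
    else:
        idx = ["-"] + list(AA_ALPHABET)
        grid = pd.DataFrame(np.nan, index=idx, columns=["+1"])
        grid.loc["-", "+1"] = lookup[wt]
        for a in AA_ALPHABET:
            m = wt + a
            if m in lookup.index:
                grid.loc[a, "+1"] = lookup[m]
    return ScanMatrix(kind=kind, wt=wt, grid=grid, missing=grid.isna())


def classify_cdegron_and_capping(
    ext: ScanMatrix,
    stable_cut: float = 0.58,
    quorum: float = 0.75,
    unstable_cut: float = 0.5,
) -> dict:
    """C-degron call from a +1-extension scan of an unstable wild type.

    A motif behaves as a C-degron when capping it — appending almost any
    single residue — stabilizes the construct: ``is_cdegron`` is true when
    at least ``quorum`` of the 20 extensions reach ``stable_cut``.
    Returns the stabilizing and tolerated amino-acid sets.
    """
    if ext.kind != "extension":
        raise ValueError("capping analysis needs an extension ScanMatrix")
    wt_psi = ext.grid.loc["-", "+1"]
    if not wt_psi < unstable_cut:
        raise ValueError(f"wild type is not unstable (PSI {wt_psi:.3f}); capping analysis undefined")
    col = ext.grid["+1"]
    stabilizing = {a for a in AA_ALPHABET if not isnan(col[a]) and col[a] >= stable_cut}
    tolerated = {a for a in AA_ALPHABET if not isnan(col[a]) and col[a] < stable_cut}
    return {
        "is_cdegron": len(stabilizing) >= quorum * 20,
        "stabilizing_set": stabilizing,
        "tolerated_set": tolerated,
        "n_missing": int(col[list(AA_ALPHABET)].isna().sum()),
    }


# -- colony fluorescence screens ---------------------------------------------


def _neighbor_means(df: pd.DataFrame, row: int, col: int, role: str, radius: int) -> tuple[float, float]:
    near = df[
        (df["role"] == role)
        & (df["row"].sub(row).abs() <= radius)
        & (df["col"].sub(col).abs() <= radius)
    ]
    if len(near) == 0:
        raise ValueError(f"sample colony at ({row},{col}) has no neighboring {role} colony")
    return float(near["green"].mean()), float(near["red"].mean())


def colony_screen_analysis(
    colonies: pd.DataFrame,
    wt_control_label: str,
    neighbor_radius: int = 2,
    ratio_threshold: float = 1.1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-strain stabilization calls from a plate of colony fluorescence.

    ``colonies`` is a tidy plate: columns row, col, strain, role
    (sample/control/reference), green, red. Sample intensities are
    background-corrected by the mean of neighboring control (non-fluorescent)
    colonies, normalized by the mean of neighboring background-corrected
    reference colonies, and summarized as red/green ratios per replicate.
    Each strain is compared to ``wt_control_label`` with a two-sided t-test
    on ratios; BH adjustment across strains; a strain is called stabilized
    when padj < alpha and its mean ratio exceeds ``ratio_threshold`` times
    the wild-type mean.
    """
    required = {"row", "col", "strain", "role", "green", "red"}
    if not required <= set(colonies.columns):
        raise ValueError(f"colonies table needs columns {sorted(required)}")
    samples = colonies[colonies["role"] == "sample"]
    rows = []
    for rec in samples.itertuples():
        bg_g, bg_r = _neighbor_means(colonies, rec.row, rec.col, "control", neighbor_radius)
        ref = colonies[
            (colonies["role"] == "reference")
            & (colonies["row"].sub(rec.row).abs() <= neighbor_radius)
            & (colonies["col"].sub(rec.col).abs() <= neighbor_radius)
        ]
        if len(ref) == 0:
            raise ValueError(f"sample colony at ({rec.row},{rec.col}) has no neighboring reference colony")
        ref_g = float((ref["green"] - bg_g).mean())
        ref_r = float((ref["red"] - bg_r).mean())
        g = rec.green - bg_g
        r = rec.red - bg_r
        if g <= 0 or r <= 0 or ref_g <= 0 or ref_r <= 0:
            rows.append({"strain": rec.strain, "green": np.nan, "ratio": np.nan, "flag": "nonpositive"})
            continue
        g_n, r_n = g / ref_g, r / ref_r
        rows.append({"strain": rec.strain, "green": g_n, "ratio": r_n / g_n, "flag": ""})
    reps = pd.DataFrame(rows)
    reps_ok = reps[reps["flag"] == ""]
    if wt_control_label not in set(reps_ok["strain"]):
        raise ValueError(f"wild-type control strain {wt_control_label!r} not found among samples")
    wt_ratio = reps_ok.loc[reps_ok["strain"] == wt_control_label, "ratio"].to_numpy()
    wt_green = reps_ok.loc[reps_ok["strain"] == wt_control_label, "green"].to_numpy()
    out = []
    for strain, grp in reps_ok.groupby("strain"):
        ratios = grp["ratio"].to_numpy()
        fold_ratio = float(ratios.mean() / wt_ratio.mean())
        fold_green = float(grp["green"].mean() / wt_green.mean())
        if strain == wt_control_label:
            p = 1.0
        elif len(ratios) >= 2 and len(wt_ratio) >= 2:
            p = float(stats.ttest_ind(ratios, wt_ratio).pvalue)
            if isnan(p):  # zero variance in both groups
                p = 1.0 if np.isclose(ratios.mean(), wt_ratio.mean()) else 0.0
        else:
            p = np.nan
        out.append(
            {
                "strain": strain,
                "n_replicates": len(ratios),
                "log2_green": np.log2(fold_green),
                "log2_ratio": np.log2(fold_ratio),
                "ratio_fold": fold_ratio,
                "p": p,
            }
        )
    res = pd.DataFrame(out)
    tested = res["p"].notna()
    res["padj"] = np.nan
    if tested.any():
        res.loc[tested, "padj"] = multipletests(res.loc[tested, "p"], method="fdr_bh")[1]
    res["stabilized"] = (res["padj"] < alpha) & (res["ratio_fold"] > ratio_threshold)
    return res
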