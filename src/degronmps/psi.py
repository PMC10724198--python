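"""Protein stability index (PSI) computation and replicate statistics.

The PSI of a variant is the cell-weighted average of the stability-bin
fraction indices, scaled between 0 (all cells in the least stable bin) and
1 (all cells in the most stable bin). Read counts per bin are first
converted to estimated cell numbers: the read share of the variant within
bin b (r_vb / R_b) times the number of cells sorted into that bin (c_b).
With bin fraction indices f_b,

    n_vb = (r_vb / R_b) * c_b
    PSI_v = sum_b n_vb * f_b / sum_b n_vb

Bins with zero total reads contribute nothing. Variants with <= min_total_reads
reads summed over bins are flagged ``low_reads`` and excluded from defaults
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .amplicon import CountMatrix

PSI_COLUMNS = ["peptide", "psi", "total_reads", "se", "n_reps", "flags"]


@dataclass
class BinScheme:
    """Per-bin sorted-cell counts and the bin fraction indices f_b.

    f_b defaults to a linear ramp (b-1)/(B-1): the endpoints 0 and 1 are
    fixed by the PSI scale, linear spacing is the simplest interior choice.
    """

    n_bins: int
    cell_counts: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")
        self.cell_counts = np.asarray(self.cell_counts, dtype=float)
        if self.cell_counts.shape != (self.n_bins,):
            raise ValueError("cell_counts must have one entry per bin")
        if (self.cell_counts < 0).any():
            raise ValueError("cell counts must be >= 0")
        if self.weights is None:
            self.weights = np.linspace(0.0, 1.0, self.n_bins)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (self.n_bins,):
                raise ValueError("weights must have one entry per bin")
            if self.weights[0] != 0.0 or self.weights[-1] != 1.0 or not np.all(np.diff(self.weights) > 0):
                raise ValueError("weights must increase strictly from 0 to 1")


def bin_scheme_to_yaml(scheme: BinScheme, path) -> None:
    import yaml

    block = {
        "n_bins": scheme.n_bins,
        "cell_counts": [float(c) for c in scheme.cell_counts],
        "weights": [float(w) for w in scheme.weights],
    }
    with open(path, "w") as fh:
        yaml.safe_dump({"bin_scheme": block}, fh)


def bin_scheme_from_yaml(path) -> BinScheme:
    import yaml

    with open(path) as fh:
        block = yaml.safe_load(fh)["bin_scheme"]
    return BinScheme(
        n_bins=block["n_bins"],
        cell_counts=np.array(block["cell_counts"]),
        weights=np.array(block["weights"]),
    )


def compute_psi(
    cm: CountMatrix, bins: BinScheme | None = None, min_total_reads: int = 10
) -> pd.DataFrame:
    """PSI per variant of ``cm`` under ``bins`` (defaults to cm.cell_counts).

    Returns a DataFrame with columns peptide, psi, total_reads, se, n_reps,
    flags. Variants with no reads at all get psi = NaN and flag ``no_reads``;
    variants at or below ``min_total_reads`` total reads are flagged
    ``low_reads`` (the default filter keeps variants with *more than*
    ``min_total_reads`` reads).
    """
    if bins is None:
        if cm.cell_counts is None:
            raise ValueError("no BinScheme given and CountMatrix has no cell counts")
        bins = BinScheme(n_bins=cm.n_bins, cell_counts=cm.cell_counts)
    if bins.n_bins != cm.n_bins:
        raise ValueError("BinScheme bin count differs from CountMatrix")
    r = cm.counts.astype(float)
    R_b = r.sum(axis=0)
    share = np.divide(r, R_b, out=np.zeros_like(r), where=R_b > 0)
    n_vb = share * bins.cell_counts
    denom = n_vb.sum(axis=1)
    numer = n_vb @ bins.weights
    psi = np.divide(numer, denom, out=np.full_like(denom, np.nan), where=denom > 0)
    total = cm.counts.sum(axis=1)
    flags = np.where(total == 0, "no_reads", np.where(total <= min_total_reads, "low_reads", ""))
    return pd.DataFrame(
        {
            "peptide": cm.variants,
            "psi": psi,
            "total_reads": total,
            "se": np.nan,
            "n_reps": 1,
            "flags": flags,
        }
    )


def filter_psi(table: pd.DataFrame) -> pd.DataFrame:
    """Drop flagged (no_reads / low_reads) rows."""
    return table[table["flags"] == ""].reset_index(drop=True)


def combine_replicates(tables: list[pd.DataFrame], min_total_reads: int = 10) -> pd.DataFrame:
    """Outer-join replicate PSI tables; mean PSI, sample SE, pooled reads.

    A peptide failing the read filter in an individual replicate is still
    used if present; the low_reads flag is re-derived from the pooled total.
    """
    if not tables:
        raise ValueError("need at least one PSI table")
    frames = []
    for i, t in enumerate(tables):
        f = t.loc[t["flags"] != "no_reads", ["peptide", "psi", "total_reads"]].copy()
        f["rep"] = i
        frames.append(f)
    longf = pd.concat(frames, ignore_index=True)
    g = longf.groupby("peptide", sort=True)
    out = g.agg(
        psi=("psi", "mean"),
        total_reads=("total_reads", "sum"),
        n_reps=("psi", "count"),
        sd=("psi", "std"),
    ).reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n_reps"])
    out["flags"] = np.where(out["total_reads"] <= min_total_reads, "low_reads", "")
    return out[PSI_COLUMNS]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone in rank, capped at 1)."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def differential_psi(
    wt: list[pd.DataFrame],
    mut: list[pd.DataFrame],
    moderation: str = "shrink",
    shrink_weight: float = 0.5,
) -> pd.DataFrame:
    """Per-peptide two-group comparison of mutant vs wild-type PSIs.

    Equal-variance two-sample t-test on replicate PSIs per peptide;
    ``moderation='shrink'`` replaces each peptide's pooled variance with a
    convex combination (weight ``shrink_weight`` on the peptide) of it and
    the across-peptide mean pooled variance, stabilizing near-zero
    replicate variances. p-values are BH-adjusted over tested peptides.
    Peptides with fewer than 2 replicates in either group keep their delta
    but get missing p/padj.
    """
    if moderation not in ("none", "shrink"):
        raise ValueError(f"unknown moderation {moderation!r}")

    def _collect(tables):
        frames = []
        for i, t in enumerate(tables):
            f = t.loc[t["flags"] == "", ["peptide", "psi"]].copy()
            f["rep"] = i
            frames.append(f)
        return pd.concat(frames, ignore_index=True).groupby("peptide")["psi"]

    gw, gm = _collect(wt), _collect(mut)
    sw = pd.DataFrame({"mean_wt": gw.mean(), "var_wt": gw.var(ddof=1), "n_wt": gw.count()})
    sm = pd.DataFrame({"mean_mut": gm.mean(), "var_mut": gm.var(ddof=1), "n_mut": gm.count()})
    df = sw.join(sm, how="inner").reset_index()
    df["delta"] = df["mean_mut"] - df["mean_wt"]

    testable = (df["n_wt"] >= 2) & (df["n_mut"] >= 2)
    n1, n2 = df["n_wt"].to_numpy(float), df["n_mut"].to_numpy(float)
    dof = n1 + n2 - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = ((n1 - 1) * df["var_wt"] + (n2 - 1) * df["var_mut"]) / dof
    pooled = pooled.to_numpy(float)
    flags = np.array([""] * len(df), dtype=object)
    mean_pooled = np.nanmean(pooled[testable.to_numpy()]) if testable.any() else np.nan
    if moderation == "shrink":
        var_use = shrink_weight * pooled + (1 - shrink_weight) * mean_pooled
    else:
        var_use = pooled.copy()
        zero = testable.to_numpy() & (pooled <= 0)
        var_use[zero] = mean_pooled
        flags[zero] = "pooled_var_fallback"
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = df["delta"].to_numpy() / np.sqrt(var_use * (1 / n1 + 1 / n2))
    p = np.full(len(df), np.nan)
    mask = testable.to_numpy() & np.isfinite(tstat) & (dof > 0)
    p[mask] = 2 * stats.t.sf(np.abs(tstat[mask]), dof[mask])
    # identical groups with zero shrunken variance -> 0/0; a null effect
    degenerate = testable.to_numpy() & ~np.isfinite(tstat) & (df["delta"].abs().to_numpy() == 0)
    p[degenerate] = 1.0
    padj = np.full(len(df), np.nan)
    tested = np.isfinite(p)
    if tested.any():
        padj[tested] = multipletests(p[tested], method="fdr_bh")[1]
    out = df[["peptide", "mean_wt", "mean_mut", "delta"]].copy()
    out.columns = ["peptide", "psi_wt", "psi_mut", "delta"]
    out["p"] = p
    out["padj"] = padj
    out["flags"] = flags
    return out


def psi_distribution_stats(table: pd.DataFrame, k: float = 3.7, scaled: bool = False) -> dict:
    """Median, MAD, dispersion d = k*MAD and tail fractions of a PSI table.

    MAD is the raw median absolute deviation by default (``scaled`` applies
    the 1.4826 normal-consistency factor). Fractions are computed over
    non-flagged peptides.
    """
    psis = filter_psi(table)["psi"].to_numpy()
    if psis.size < 2:
        raise ValueError("need at least 2 non-flagged peptides")
    med = float(np.median(psis))
    mad = float(np.median(np.abs(psis - med)))
    if scaled:
        mad *= 1.4826
    d = k * mad
    return {
        "median": med,
        "mad": mad,
        "d": d,
        "frac_above": float(np.mean(psis > med + d)),
        "frac_below": float(np.mean(psis < med - d)),
    }


def unstable_cell_fraction(
    cells: pd.DataFrame, gate_threshold: float, ratio_cut: float = 0.5
) -> float:
    """Percentage of sfGFP-gated cells whose red/green ratio is below ``ratio_cut``.

    ``cells`` needs columns ``green`` and ``red``; cells with green fluorescence
    above ``gate_threshold`` (e.g. the maximum of a non-fluorescent control)
    are gated in, and ratios are taken without background correction.
    """
    gated = cells[cells["green"] > gate_threshold]
    if len(gated) == 0:
        raise ValueError("no cells pass the sfGFP gate")
    frac = np.mean(gated["red"].to_numpy() / gated["green"].to_numpy() < ratio_cut)
    return float(100.0 * frac)


def write_psi_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_psi_table(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=["nan", ""])
    t["flags"] = t["flags"].fillna("")
    return t
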