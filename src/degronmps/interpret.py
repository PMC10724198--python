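"""Permutation-Shapley attribution, attribution clustering and motif discovery.

Shapley values are estimated by the permutation walk: features are switched
one at a time, in random order, from a background instance's values to the
explained instance's values, and each feature is credited with the induced
change in the model's unstable-class probability. Averaging the credits over
permutations (with the reversed order of every permutation included as an
antithetic pair) gives the contribution vector; its sum telescopes to
f(x) - f(background) per walk, so local accuracy holds up to Monte-Carlo
error in the background average.

Attribution vectors of unstable peptides are clustered with k-means; a
cluster whose mean one-hot contribution exceeds a threshold anywhere at
positions -5..-1 is flagged as a potential C-degron motif, summarized by a
sequence logo of mean contributions and a representative peptide (the member
with the highest summed Smith-Waterman local-alignment score to the rest of
the cluster).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from sklearn.cluster import KMeans

from .features import FeatureLayout
from .peptides import AA_ALPHABET


@dataclass
class ShapExplanation:
    peptide: str
    values: np.ndarray          # phi_j per feature
    base_value: float           # mean model output over the background draws
    explained_output: float     # unstable-class probability of the peptide


def permutation_shap(
    predict_fn,
    x: np.ndarray,
    background: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
    antithetic: bool = True,
    peptide: str = "",
    batch_perms: int = 8,
) -> ShapExplanation:
    """Permutation-Shapley contributions of one instance ``x``.

    ``predict_fn`` maps an (n, d) feature matrix to the explained scalar
    output per row (here: unstable-class probability). One background row is
    drawn per permutation (interventional/marginal conditioning); walks for
    several permutations are batched into single model calls.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0:
        raise ValueError("background set is empty")
    x = np.asarray(x, dtype=float).ravel()
    d = x.size
    rng = np.random.default_rng(seed)
    credits = np.zeros(d)
    n_walks = 0
    base_sum = 0.0
    n_base = 0
    tril_r, tril_c = np.tril_indices(d)
    for start in range(0, n_perm, batch_perms):
        chunk = min(batch_perms, n_perm - start)
        orders = []
        bgs = []
        for _ in range(chunk):
            pi = rng.permutation(d)
            b = background[rng.integers(0, background.shape[0])]
            orders.append(pi)
            bgs.append(b)
            if antithetic:
                orders.append(pi[::-1])
                bgs.append(b)
        # one walk = d+1 rows: row k has features pi[:k] switched from b to x
        walks = []
        for pi, b in zip(orders, bgs):
            steps = np.tile(b, (d + 1, 1))
            mask = np.zeros((d + 1, d), dtype=bool)
            mask[tril_r + 1, pi[tril_c]] = True
            steps[mask] = np.broadcast_to(x, (d + 1, d))[mask]
            walks.append(steps)
        out = np.asarray(predict_fn(np.vstack(walks)), dtype=float).reshape(len(orders), d + 1)
        for w, pi in enumerate(orders):
            credits[pi] += np.diff(out[w])
            n_walks += 1
        stride = 2 if antithetic else 1
        base_sum += out[::stride, 0].sum()  # f(background draw), one per permutation
        n_base += chunk
    phi = credits / n_walks
    f_x = float(np.asarray(predict_fn(x[None, :])).ravel()[0])
    return ShapExplanation(
        peptide=peptide,
        values=phi,
        base_value=float(base_sum / n_base),
        explained_output=f_x,
    )


def explain_peptides(
    predict_fn,
    X: np.ndarray,
    peptides: list[str],
    background: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
    antithetic: bool = True,
) -> list[ShapExplanation]:
    """Explain each row of X; per-peptide seeds derive from ``seed``."""
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(peptides))
    return [
        permutation_shap(
            predict_fn, X[i], background, n_perm=n_perm,
            seed=int(child_seeds[i] % (2**31)), antithetic=antithetic, peptide=p,
        )
        for i, p in enumerate(peptides)
    ]


# -- clustering ---------------------------------------------------------------


@dataclass
class ClusterSet:
    k: int
    peptides: list[str]
    assignment: np.ndarray       # cluster index per peptide
    means: np.ndarray            # (k, d) mean contribution vectors
    wss: float
    wss_curve: dict[int, float] = field(default_factory=dict)

    def members(self, cluster: int) -> list[str]:
        return [p for p, a in zip(self.peptides, self.assignment) if a == cluster]


def _contribution_matrix(explanations: list[ShapExplanation]) -> tuple[list[str], np.ndarray]:
    return [e.peptide for e in explanations], np.stack([e.values for e in explanations])


def cluster_explanations(
    explanations: list[ShapExplanation],
    k: int | str = "auto",
    k_range=range(1, 16),
    seed: int = 0,
    n_restarts: int = 5,
) -> ClusterSet:
    """k-means on full contribution vectors; ``k='auto'`` picks the WSS elbow
    (maximum second difference of the within-cluster sum of squares curve)."""
    peptides, M = _contribution_matrix(explanations)
    n = len(peptides)
    wss_curve: dict[int, float] = {}
    if k == "auto":
        ks = [kk for kk in k_range if kk <= n]
        if len(ks) < 3:
            raise ValueError("k_range too small for elbow selection")
        fits = {}
        for kk in ks:
            km = KMeans(n_clusters=kk, n_init=n_restarts, random_state=seed).fit(M)
            fits[kk] = km
            wss_curve[kk] = float(km.inertia_)
        wss_vals = np.array([wss_curve[kk] for kk in ks])
        second_diff = wss_vals[:-2] - 2 * wss_vals[1:-1] + wss_vals[2:]
        k = ks[1 + int(np.argmax(second_diff))]
        km = fits[k]
    else:
        if k > n:
            raise ValueError(f"k={k} exceeds {n} explanations")
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(M)
        wss_curve[k] = float(km.inertia_)
    means = np.stack([M[km.labels_ == c].mean(axis=0) for c in range(k)])
    return ClusterSet(
        k=int(k), peptides=peptides, assignment=km.labels_.copy(),
        means=means, wss=float(km.inertia_), wss_curve=wss_curve,
    )


# -- motif selection and summaries -------------------------------------------


def summarize_and_select_motifs(
    cs: ClusterSet,
    layout: FeatureLayout,
    score_threshold: float = 0.05,
    positions: tuple[int, int] = (-5, -1),
) -> dict[int, dict]:
    """Per-cluster logos and the potential-C-degron motif flag.

    The sequence logo is the cluster's mean one-hot-block contribution
    reshaped to (position x amino acid); the cluster is flagged as a motif
    when any logo entry at ``positions`` (inclusive C-terminal window)
    exceeds ``score_threshold``. Positive values push toward the unstable
    prediction.
    """
    L = layout.length
    lo, hi = positions
    window = [p for p in range(lo, hi + 1) if -L <= p <= -1]
    out: dict[int, dict] = {}
    for c in range(cs.k):
        mean = cs.means[c]
        onehot = mean[layout.onehot_slice()].reshape(L, 20)
        logo = pd.DataFrame(onehot, index=layout.positions(), columns=list(AA_ALPHABET))
        pos_block = mean[layout.positional_slice()].reshape(len(layout.scales), L)
        prop_logo = pd.DataFrame(pos_block, index=list(layout.scales), columns=layout.positions())
        global_bars = pd.Series(mean[layout.global_slice()], index=list(layout.scales))
        sub = logo.loc[window]
        motif_flag = bool((sub.to_numpy() > score_threshold).any())
        top_idx = np.unravel_index(np.argmax(sub.to_numpy()), sub.shape)
        out[c] = {
            "sequence_logo": logo,
            "property_logo": prop_logo,
            "global_bars": global_bars,
            "motif_flag": motif_flag,
            "top_entry": (window[top_idx[0]], AA_ALPHABET[top_idx[1]]),
            "top_score": float(sub.to_numpy()[top_idx]),
        }
    return out


# -- representative peptides --------------------------------------------------


def make_aligner(matrix: str = "BLOSUM62", gap_open: float = 10.0, gap_extend: float = 0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def sw_score(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Smith-Waterman local alignment score (BLOSUM62, affine 10/0.5)."""
    if aligner is None:
        aligner = make_aligner()
    return float(aligner.score(a, b))


def representative_peptide(members: list[str], aligner: Align.PairwiseAligner | None = None) -> str:
    """Member with the maximal summed local-alignment score to all others.

    Ties break lexicographically; a singleton cluster returns its member.
    """
    if not members:
        raise ValueError("empty cluster")
    if len(members) == 1:
        return members[0]
    if aligner is None:
        aligner = make_aligner()
    n = len(members)
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = sw_score(members[i], members[j], aligner)
            scores[i, j] = scores[j, i] = s
    totals = scores.sum(axis=1)
    best = totals.max()
    candidates = sorted(members[i] for i in range(n) if totals[i] == best)
    return candidates[0]


def cluster_label_enrichment(
    cs_or_assignment,
    labels: dict[str, bool] | pd.Series,
    flagged_clusters: set[int],
) -> dict:
    """Fold enrichment of labeled peptides inside flagged clusters.

    freq_in = labeled/total within flagged clusters, freq_out likewise over
    the remaining clusters, fold = freq_in/freq_out (flagged undefined when
    freq_out is zero).
    """
    if not flagged_clusters:
        raise ValueError("no flagged clusters")
    if isinstance(cs_or_assignment, ClusterSet):
        peptides, assignment = cs_or_assignment.peptides, cs_or_assignment.assignment
    else:
        peptides, assignment = cs_or_assignment
    labels = pd.Series(labels)
    missing = [p for p in peptides if p not in labels.index]
    if missing:
        raise ValueError(f"labels missing for {len(missing)} clustered peptides")
    in_mask = np.array([a in flagged_clusters for a in assignment])
    lab = labels.loc[list(peptides)].to_numpy(dtype=bool)
    n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
    if n_in == 0 or n_out == 0:
        raise ValueError("flagged clusters must be a proper non-empty subset")
    freq_in = lab[in_mask].mean()
    freq_out = lab[~in_mask].mean()
    result = {
        "freq_in": float(freq_in),
        "freq_out": float(freq_out),
        "n_in": n_in,
        "n_out": n_out,
        "labeled_in": int(lab[in_mask].sum()),
        "labeled_out": int(lab[~in_mask].sum()),
    }
    if freq_out == 0:
        result["fold"] = np.nan
        result["flag"] = "undefined"
    else:
        result["fold"] = float(freq_in / freq_out)
        result["flag"] = ""
    return result
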