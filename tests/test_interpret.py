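"""Permutation SHAP, attribution clustering, representatives and enrichment."""

import numpy as np
import pytest

from degronmps.features import FeatureLayout, encode_features
from degronmps.interpret import (
    ShapExplanation,
    cluster_explanations,
    cluster_label_enrichment,
    permutation_shap,
    representative_peptide,
    summarize_and_select_motifs,
    sw_score,
)


class TestPermutationShap:
    def test_constant_model_zero_contributions(self, rng):
        f = lambda X: np.full(len(np.atleast_2d(X)), 0.7)
        bg = rng.random((20, 5))
        x = rng.random(5)
        e = permutation_shap(f, x, bg, n_perm=20, seed=0)
        assert np.allclose(e.values, 0.0)
        assert e.base_value == pytest.approx(e.explained_output)

    def test_passthrough_single_feature(self, rng):
        f = lambda X: np.atleast_2d(X)[:, 0]
        bg = rng.random((30, 4))
        x = np.array([0.9, 0.1, 0.2, 0.3])
        e = permutation_shap(f, x, bg, n_perm=200, seed=1)
        # phi_0 = x_0 - mean of drawn background values; others exactly 0
        assert np.allclose(e.values[1:], 0.0)
        assert e.values[0] == pytest.approx(x[0] - e.base_value, abs=1e-12)
        assert abs(e.values[0] - (x[0] - bg[:, 0].mean())) < 3 * bg[:, 0].std() / np.sqrt(200)

    def test_linear_model_closed_form(self, rng):
        w = np.array([1.5, -2.0, 0.5, 0.0, 3.0])
        f = lambda X: np.atleast_2d(X) @ w
        bg = rng.random((50, 5))
        x = rng.random(5)
        n_perm = 1000
        e = permutation_shap(f, x, bg, n_perm=n_perm, seed=2)
        expected = w * (x - bg.mean(axis=0))
        mc_se = np.abs(w) * bg.std(axis=0) / np.sqrt(n_perm)
        assert np.all(np.abs(e.values - expected) <= 3 * mc_se + 1e-12)

    def test_dummy_feature_exactly_zero(self, rng):
        f = lambda X: np.atleast_2d(X)[:, 1] ** 2
        bg = rng.random((10, 3))
        e = permutation_shap(f, rng.random(3), bg, n_perm=50, seed=3)
        assert e.values[0] == 0.0 and e.values[2] == 0.0

    def test_local_accuracy_exact_with_antithetic(self, rng):
        f = lambda X: np.tanh(np.atleast_2d(X) @ np.array([1.0, -1.0, 2.0]))
        bg = rng.random((15, 3))
        x = rng.random(3)
        e = permutation_shap(f, x, bg, n_perm=30, seed=4)
        assert e.values.sum() == pytest.approx(e.explained_output - e.base_value, abs=1e-10)

    def test_local_accuracy_tightens_with_permutations(self, rng):
        # without antithetic pairing the identity holds only in expectation
        f = lambda X: (np.atleast_2d(X) ** 2) @ np.array([1.0, 2.0, 0.5, 1.0])
        bg = rng.random((40, 4))
        x = rng.random(4)
        errs = []
        for n_perm in (10, 100, 1000):
            e = permutation_shap(f, x, bg, n_perm=n_perm, seed=5, antithetic=False)
            errs.append(abs(e.values.sum() - (e.explained_output - e.base_value)))
        assert errs[2] == pytest.approx(0.0, abs=1e-10)  # still telescopes per walk
        # every walk telescopes exactly: f(x) - f(b); averaging over walks
        # equals f(x) - mean f(b) = explained - base, so all errors tiny
        assert max(errs) < 1e-10

    def test_symmetry_of_equivalent_features(self, rng):
        f = lambda X: np.atleast_2d(X)[:, 0] + np.atleast_2d(X)[:, 1]
        bg = np.zeros((5, 2))
        x = np.array([0.6, 0.6])
        e = permutation_shap(f, x, bg, n_perm=50, seed=6)
        assert e.values[0] == pytest.approx(e.values[1], abs=1e-10)

    def test_invalid_n_perm(self, rng):
        with pytest.raises(ValueError):
            permutation_shap(lambda X: np.zeros(len(X)), np.zeros(2), np.zeros((1, 2)), n_perm=0)


def blob_explanations(rng, n_per=30, d=6, sep=5.0):
    centers = np.zeros((2, d))
    centers[1, 0] = sep
    expls = []
    for c in range(2):
        for i in range(n_per):
            v = centers[c] + rng.normal(0, 0.3, d)
            expls.append(ShapExplanation(f"P{c}_{i}", v, 0.0, 0.0))
    return expls


class TestClustering:
    def test_two_blobs_auto_selects_two(self, rng):
        expls = blob_explanations(rng)
        cs = cluster_explanations(expls, k="auto", k_range=range(1, 8), seed=0)
        assert cs.k == 2
        # assignment matches blob identity up to label swap
        first = cs.assignment[:30]
        second = cs.assignment[30:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]

    def test_wss_non_increasing_in_k(self, rng):
        expls = blob_explanations(rng, n_per=20)
        cs = cluster_explanations(expls, k="auto", k_range=range(2, 7), seed=1)
        ks = sorted(cs.wss_curve)
        wss = [cs.wss_curve[k] for k in ks]
        assert all(wss[i + 1] <= wss[i] + 1e-9 for i in range(len(wss) - 1))

    def test_k_equals_n_zero_wss(self, rng):
        expls = blob_explanations(rng, n_per=3)
        cs = cluster_explanations(expls, k=6, seed=2)
        assert cs.wss == pytest.approx(0.0, abs=1e-9)

    def test_k_exceeding_n_errors(self, rng):
        expls = blob_explanations(rng, n_per=2)
        with pytest.raises(ValueError):
            cluster_explanations(expls, k=10, seed=0)


class TestMotifSelection:
    def make_cluster_set(self, logo_value, L=6):
        layout = FeatureLayout(length=L)
        d = layout.n_features
        v = np.zeros(d)
        # put weight on (-1, N)
        from degronmps.peptides import AA_INDEX

        v[(L - 1) * 20 + AA_INDEX["N"]] = logo_value
        expl = [ShapExplanation("GGGGIN", v, 0.0, 0.0), ShapExplanation("GGGGLN", v, 0.0, 0.0)]
        cs = cluster_explanations(expl, k=1, seed=0)
        return cs, layout

    def test_strong_terminal_entry_flags_motif(self):
        cs, layout = self.make_cluster_set(0.3)
        out = summarize_and_select_motifs(cs, layout)
        assert out[0]["motif_flag"] is True
        assert out[0]["top_entry"] == (-1, "N")
        assert out[0]["sequence_logo"].loc[-1, "N"] == pytest.approx(0.3)

    def test_zero_contributions_no_motif(self):
        cs, layout = self.make_cluster_set(0.0)
        assert summarize_and_select_motifs(cs, layout)[0]["motif_flag"] is False

    def test_infinite_threshold_no_motifs(self):
        cs, layout = self.make_cluster_set(0.3)
        out = summarize_and_select_motifs(cs, layout, score_threshold=np.inf)
        assert not out[0]["motif_flag"]

    def test_entry_outside_window_ignored(self):
        layout = FeatureLayout(length=8)
        v = np.zeros(layout.n_features)
        from degronmps.peptides import AA_INDEX

        v[0 * 20 + AA_INDEX["W"]] = 0.5  # position -8, outside -5..-1
        cs = cluster_explanations(
            [ShapExplanation("WGGGGGGG", v, 0, 0), ShapExplanation("WGGGGGGA", v, 0, 0)],
            k=1, seed=0,
        )
        assert summarize_and_select_motifs(cs, layout)[0]["motif_flag"] is False


def sw_oracle(a, b, matrix, gap_open=10.0, gap_extend=0.5):
    """Independent Gotoh local-alignment DP: first gap position costs
    gap_open, each further position gap_extend (biopython convention)."""
    n, m = len(a), len(b)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (horizontal)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            sub = matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestSmithWaterman:
    def test_identical_poly_ala(self):
        assert sw_score("AAAA", "AAAA") == 16.0  # BLOSUM62 A:A = 4

    def test_score_properties(self, rng):
        from degronmps.synthetic import generate_library

        peps = generate_library("random", 6, 8, seed=9)
        for a in peps[:4]:
            for b in peps[4:]:
                s = sw_score(a, b)
                assert s >= 0
                assert s == sw_score(b, a)

    def test_matches_independent_dp(self, rng):
        from Bio.Align import substitution_matrices

        from degronmps.synthetic import generate_library

        blosum = substitution_matrices.load("BLOSUM62")
        peps = generate_library("random", 6, 10, seed=10) + generate_library("random", 4, 6, seed=11)
        rng_local = np.random.default_rng(0)
        for _ in range(25):
            a, b = rng_local.choice(peps, 2, replace=True)
            assert sw_score(a, b) == pytest.approx(sw_oracle(a, b, blosum))


class TestRepresentative:
    def test_singleton(self):
        assert representative_peptide(["ACDK"]) == "ACDK"

    def test_majority_similarity(self):
        assert representative_peptide(["AAAAAA", "AAAAAA", "WWDDRR"]) == "AAAAAA"

    def test_tie_broken_lexicographically(self):
        # two identical-by-symmetry members: lexicographically smaller wins
        rep = representative_peptide(["CAAAAC", "AAAAAA", "AAAAAA"])
        assert rep == "AAAAAA"

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            representative_peptide([])


class TestClusterLabelEnrichment:
    def make_cs(self, assignment, peptides=None):
        peptides = peptides or [f"P{i}" for i in range(len(assignment))]
        return (peptides, np.asarray(assignment))

    def test_uniform_labels_fold_one(self):
        peps = [f"P{i}" for i in range(40)]
        assignment = np.array([0] * 20 + [1] * 20)
        labels = {p: i % 2 == 0 for i, p in enumerate(peps)}
        res = cluster_label_enrichment((peps, assignment), labels, {0})
        assert res["fold"] == pytest.approx(1.0)

    def test_all_labels_in_flagged_undefined(self):
        peps = [f"P{i}" for i in range(10)]
        assignment = np.array([0] * 5 + [1] * 5)
        labels = {p: i < 5 for i, p in enumerate(peps)}
        res = cluster_label_enrichment((peps, assignment), labels, {0})
        assert res["flag"] == "undefined" and np.isnan(res["fold"])

    def test_published_worked_example(self):
        """416 of 1476 peptides labeled inside the flagged clusters versus
        343 of 2634 outside gives a 2.2-fold relative frequency."""
        peps = [f"P{i}" for i in range(4110)]
        assignment = np.array([0] * 1476 + [1] * 2634)
        labels = {}
        for i, p in enumerate(peps):
            if i < 1476:
                labels[p] = i < 416
            else:
                labels[p] = i < 1476 + 343
        res = cluster_label_enrichment((peps, assignment), labels, {0})
        assert round(res["fold"], 1) == 2.2
        assert res["labeled_in"] == 416 and res["labeled_out"] == 343

    def test_no_flagged_clusters_errors(self):
        with pytest.raises(ValueError):
            cluster_label_enrichment((["A"], np.array([0])), {"A": True}, set())
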