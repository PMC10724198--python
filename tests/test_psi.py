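"""PSI computation, replicate combination and differential testing."""

import numpy as np
import pandas as pd
import pytest

from degronmps.amplicon import CountMatrix
from degronmps.psi import (
    BinScheme,
    bh_adjust,
    combine_replicates,
    compute_psi,
    differential_psi,
    filter_psi,
    psi_distribution_stats,
    unstable_cell_fraction,
)


def make_cm(counts, cells=None, variants=None):
    counts = np.asarray(counts)
    variants = variants or [f"PEP{i}" for i in range(counts.shape[0])]
    cells = np.ones(counts.shape[1]) * 100 if cells is None else np.asarray(cells, float)
    return CountMatrix(variants, counts, level="peptide", cell_counts=cells)


def psi_oracle_matrix(counts, cells, weights):
    """Independent transcription of the PSI definition: per-bin read share
    times sorted-cell count, then the fraction-index-weighted average."""
    counts = np.asarray(counts, float)
    n_var, n_bins = counts.shape
    psis = []
    for v in range(n_var):
        num = den = 0.0
        for b in range(n_bins):
            R_b = counts[:, b].sum()
            if R_b == 0:
                continue
            n_vb = counts[v, b] / R_b * cells[b]
            num += n_vb * weights[b]
            den += n_vb
        psis.append(num / den if den > 0 else np.nan)
    return np.array(psis)


class TestComputePsi:
    def test_all_reads_most_stable_bin_gives_one(self):
        cm = make_cm([[0, 0, 0, 0, 0, 0, 0, 1000]])
        assert compute_psi(cm)["psi"].iloc[0] == 1.0

    def test_all_reads_least_stable_bin_gives_zero(self):
        cm = make_cm([[1000, 0, 0, 0, 0, 0, 0, 0]])
        assert compute_psi(cm)["psi"].iloc[0] == 0.0

    def test_two_bin_hand_example(self):
        # two variants, reads (90,10) and (10,90), equal cells: PSI 0.1 / 0.9
        cm = make_cm([[90, 10], [10, 90]], cells=[100, 100])
        psis = compute_psi(cm)["psi"].to_numpy()
        assert psis == pytest.approx([0.1, 0.9])

    def test_oracle_equivalence_random_small_matrices(self, rng):
        for _ in range(60):
            n_var = rng.integers(1, 6)
            n_bins = rng.integers(2, 5)
            counts = rng.integers(0, 40, size=(n_var, n_bins))
            cells = rng.integers(1, 200, size=n_bins).astype(float)
            cm = make_cm(counts, cells)
            scheme = BinScheme(n_bins=n_bins, cell_counts=cells)
            got = compute_psi(cm, scheme)["psi"].to_numpy()
            expected = psi_oracle_matrix(counts, cells, scheme.weights)
            assert np.allclose(got, expected, atol=1e-12, equal_nan=True)

    def test_per_bin_scaling_invariance(self, rng):
        counts = rng.integers(1, 50, size=(4, 3))
        cells = np.array([50.0, 80.0, 120.0])
        base = compute_psi(make_cm(counts, cells))["psi"].to_numpy()
        scaled = counts.copy()
        scaled[:, 1] *= 7  # common factor within a bin
        again = compute_psi(make_cm(scaled, cells))["psi"].to_numpy()
        assert np.allclose(base, again, atol=1e-12)

    def test_bin_shift_monotonicity(self, rng):
        """Moving a variant's reads to a higher-fraction bin never decreases
        its PSI when sequencing depth is proportional to sorted cells (the
        pooling scheme of the assay); bin totals are held fixed by swapping
        a read with another variant."""
        for _ in range(30):
            counts = rng.integers(0, 30, size=(3, 4)) + 1
            depth = counts.sum(axis=0)
            cells = depth * float(rng.integers(1, 20))  # cells proportional to reads
            before = compute_psi(make_cm(counts, cells))["psi"].to_numpy()
            lo, hi = sorted(rng.choice(4, size=2, replace=False))
            moved = counts.copy()
            moved[0, lo] -= 1
            moved[0, hi] += 1
            moved[1, lo] += 1  # compensating swap keeps per-bin totals fixed
            moved[1, hi] -= 1
            after = compute_psi(make_cm(moved, cells))["psi"].to_numpy()
            assert after[0] >= before[0] - 1e-12

    def test_zero_read_variant_flagged_not_propagated(self):
        cm = make_cm([[0, 0], [50, 50]])
        t = compute_psi(cm, min_total_reads=10)
        assert t.loc[0, "flags"] == "no_reads" and np.isnan(t.loc[0, "psi"])
        assert np.isfinite(t.loc[1, "psi"])

    def test_low_reads_flagged_and_filterable(self):
        cm = make_cm([[5, 5], [100, 100]])
        t = compute_psi(cm, min_total_reads=10)
        assert t.loc[0, "flags"] == "low_reads"
        assert list(filter_psi(t)["peptide"]) == ["PEP1"]

    def test_boundary_more_than_min_reads_kept(self):
        cm = make_cm([[6, 5], [5, 5]])
        t = compute_psi(cm, min_total_reads=10)
        assert t.loc[0, "flags"] == "" and t.loc[1, "flags"] == "low_reads"


def table(peptides, psis, reads=1000):
    return pd.DataFrame(
        {
            "peptide": peptides,
            "psi": psis,
            "total_reads": reads,
            "se": np.nan,
            "n_reps": 1,
            "flags": "",
        }
    )


class TestCombineReplicates:
    def test_identical_replicates(self):
        t = table(["A", "B"], [0.2, 0.8])
        out = combine_replicates([t, t.copy()])
        assert out["psi"].tolist() == [0.2, 0.8]
        assert (out["se"] == 0).all()
        assert (out["n_reps"] == 2).all()

    def test_mean_of_two(self):
        out = combine_replicates([table(["A"], [0.2]), table(["A"], [0.4])])
        assert out["psi"].iloc[0] == pytest.approx(0.3)

    def test_outer_join_keeps_partial_peptides(self):
        out = combine_replicates([table(["A", "B"], [0.2, 0.5]), table(["A"], [0.4])])
        row_b = out[out["peptide"] == "B"].iloc[0]
        assert row_b["n_reps"] == 1 and row_b["psi"] == 0.5


class TestDifferentialPsi:
    def test_null_case(self):
        reps = [table(["A", "B"], [0.3, 0.6]), table(["A", "B"], [0.31, 0.59])]
        out = differential_psi(reps, [t.copy() for t in reps])
        assert np.allclose(out["delta"], 0.0)
        assert (out["p"] > 0.9).all()

    def test_shifted_mutant_significant(self):
        wt = [table(["A", "B"], [0.2 + e, 0.6 + e]) for e in (0.0, 0.004, -0.004)]
        mut = [table(["A", "B"], [0.7 + e, 0.6 + e]) for e in (0.0, 0.004, -0.004)]
        out = differential_psi(wt, mut).set_index("peptide")
        assert out.loc["A", "delta"] == pytest.approx(0.5)
        assert out.loc["A", "padj"] < 0.05
        assert out.loc["B", "padj"] > 0.5

    def test_single_replicate_delta_without_p(self):
        out = differential_psi([table(["A"], [0.2])], [table(["A"], [0.5])])
        assert out["delta"].iloc[0] == pytest.approx(0.3)
        assert np.isnan(out["p"].iloc[0])

    def test_zero_variance_fallback_flagged(self):
        wt = [table(["A", "B"], [0.2, 0.5]), table(["A", "B"], [0.2, 0.52])]
        mut = [table(["A", "B"], [0.4, 0.5]), table(["A", "B"], [0.4, 0.52])]
        out = differential_psi(wt, mut, moderation="none").set_index("peptide")
        assert out.loc["A", "flags"] == "pooled_var_fallback"
        assert np.isfinite(out.loc["A", "p"])


class TestBHAdjust:
    def test_hand_computed_example(self):
        # p=(0.01,0.02,0.03,0.04), m=4: p_(i) * m/i = (.04,.04,.04,.04)
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_monotone_in_rank_and_bounded(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(2, 50))
            adj = bh_adjust(p)
            order = np.argsort(p)
            assert (np.diff(adj[order]) >= -1e-12).all()
            assert (adj <= 1.0 + 1e-12).all()
            assert (adj >= p - 1e-12).all()


class TestDistributionStats:
    def test_all_equal(self):
        t = table(list("ABCD"), [0.4] * 4)
        s = psi_distribution_stats(t)
        assert s["mad"] == 0 and s["frac_above"] == 0 and s["frac_below"] == 0

    def test_hand_computed_median_mad(self):
        t = table(list("ABCDE"), [0.1, 0.2, 0.3, 0.4, 0.5])
        s = psi_distribution_stats(t)
        assert s["median"] == pytest.approx(0.3)
        assert s["mad"] == pytest.approx(0.1)
        assert s["d"] == pytest.approx(0.37)

    def test_symmetric_tails_balance(self, rng):
        vals = np.concatenate([rng.normal(0.5, 0.05, 2000)])
        vals = np.clip(vals, 0, 1)
        t = table([f"P{i}" for i in range(len(vals))], vals)
        s = psi_distribution_stats(t, k=1.0)
        assert abs(s["frac_above"] - s["frac_below"]) < 0.03

    def test_scaled_mad_option(self):
        t = table(list("ABCDE"), [0.1, 0.2, 0.3, 0.4, 0.5])
        assert psi_distribution_stats(t, scaled=True)["mad"] == pytest.approx(0.14826)


class TestUnstableCellFraction:
    def test_counting(self):
        cells = pd.DataFrame(
            {"green": [10.0] * 10, "red": [4.0] * 3 + [6.0] * 7}
        )
        assert unstable_cell_fraction(cells, gate_threshold=1.0) == pytest.approx(30.0)

    def test_all_below_cut(self):
        cells = pd.DataFrame({"green": [10.0] * 5, "red": [4.0] * 5})
        assert unstable_cell_fraction(cells, 1.0) == 100.0

    def test_none_below_cut(self):
        cells = pd.DataFrame({"green": [10.0] * 5, "red": [9.0] * 5})
        assert unstable_cell_fraction(cells, 1.0) == 0.0

    def test_zero_gated_errors(self):
        cells = pd.DataFrame({"green": [0.5], "red": [0.2]})
        with pytest.raises(ValueError, match="gate"):
            unstable_cell_fraction(cells, gate_threshold=1.0)


class TestBinSchemeYaml:
    def test_round_trip(self, tmp_path):
        from degronmps.psi import bin_scheme_from_yaml, bin_scheme_to_yaml

        scheme = BinScheme(n_bins=4, cell_counts=np.array([10.0, 20.0, 5.0, 8.0]))
        path = tmp_path / "bins.yaml"
        bin_scheme_to_yaml(scheme, path)
        back = bin_scheme_from_yaml(path)
        assert back.n_bins == 4
        assert np.allclose(back.cell_counts, scheme.cell_counts)
        assert np.allclose(back.weights, scheme.weights)
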