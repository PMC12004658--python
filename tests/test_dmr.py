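"""Window partitioning, Fisher's exact test and the four DMR filters."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

import rootmeth as rm
from rootmeth.dmr import WindowCounts, summarize_dmrs, venn_counts

from conftest import make_track


def fisher_oracle(mc_a, cov_a, mc_b, cov_b):
    """Independent full-enumeration two-sided Fisher p in exact rationals."""
    n, c1 = cov_a + cov_b, mc_a + mc_b
    if n == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = comb(n, c1)
    pmf = {
        k: Fraction(comb(cov_a, k) * comb(cov_b, c1 - k), denom)
        for k in range(max(0, c1 - cov_b), min(cov_a, c1) + 1)
    }
    obs = pmf[mc_a]
    return float(sum(p for p in pmf.values() if p <= obs))


class TestPartitionWindows:
    def test_even_and_ragged_lengths(self):
        w = rm.partition_windows({"chr1": 100})
        assert list(zip(w["start"], w["end"])) == [(0, 50), (50, 100)]
        w = rm.partition_windows({"chr1": 101})
        assert len(w) == 3 and (w["start"].iloc[-1], w["end"].iloc[-1]) == (100, 101)

    @given(st.integers(1, 5000), st.integers(1, 200))
    @settings(max_examples=100, deadline=None)
    def test_windows_tile_exactly(self, length, width):
        w = rm.partition_windows({"chr1": length}, width)
        assert w["start"].iloc[0] == 0 and w["end"].iloc[-1] == length
        assert (w["start"].iloc[1:].to_numpy() == w["end"].iloc[:-1].to_numpy()).all()
        assert ((w["end"] - w["start"]).iloc[:-1] == width).all()


class TestWindowCounts:
    def test_boundary_is_half_open(self):
        # 1-based position 50 is the last base of window [0,50); 51 the first of [50,100)
        t_in = make_track([("chr1", 50, "+", "CHH", 2, 10)])
        t_out = make_track([("chr1", 51, "+", "CHH", 2, 10)])
        empty = make_track([])
        for track, widx in ((t_in, 0), (t_out, 1)):
            counts = rm.window_counts([track], [empty], {"chr1": 100}, "CHH")
            assert counts.cov_a[0, widx] == 10
            assert counts.cov_a.sum() == 10

    def test_uncovered_window_flagged(self):
        counts = rm.window_counts(
            [make_track([("chr1", 60, "+", "CHH", 2, 10)])],
            [make_track([("chr1", 60, "+", "CHH", 1, 10)])],
            {"chr1": 100},
            "CHH",
        )
        m_a, _ = counts.pooled_levels()
        assert counts.informative_a[0] == 0 and np.isnan(m_a[0])
        assert m_a[1] == pytest.approx(0.2)


class TestFisherExact:
    def test_no_association(self):
        assert rm.fisher_exact_test(5, 10, 5, 10) == 1.0

    def test_symmetry(self):
        assert rm.fisher_exact_test(3, 12, 9, 15) == rm.fisher_exact_test(9, 15, 3, 12)

    def test_extreme_table_matches_enumeration(self):
        p = rm.fisher_exact_test(0, 20, 20, 20)
        assert p == pytest.approx(fisher_oracle(0, 20, 20, 20), abs=1e-15)
        assert p < 1e-9

    def test_degenerate_margins(self):
        assert rm.fisher_exact_test(0, 0, 0, 0) == 1.0
        assert rm.fisher_exact_test(0, 10, 0, 12) == 1.0
        assert rm.fisher_exact_test(10, 10, 12, 12) == 1.0

    def test_against_scipy_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 40, size=4)
            ours = rm.fisher_exact_test(a, a + b, c, c + d)
            ref = scipy_fisher([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_against_enumeration_oracle_small_sweep(self):
        for n in range(0, 21):
            for cov_a in range(n + 1):
                cov_b = n - cov_a
                for mc_a in range(cov_a + 1):
                    for mc_b in range(cov_b + 1):
                        assert rm.fisher_exact_test(mc_a, cov_a, mc_b, cov_b) == pytest.approx(
                            fisher_oracle(mc_a, cov_a, mc_b, cov_b), abs=1e-12
                        )

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            rm.fisher_exact_test(5, 3, 0, 2)


def _counts_from_arrays(mc_a, cov_a, mc_b, cov_b, context="CHH", width=50):
    mc_a, cov_a = np.atleast_2d(mc_a), np.atleast_2d(cov_a)
    mc_b, cov_b = np.atleast_2d(mc_b), np.atleast_2d(cov_b)
    n = mc_a.shape[1]
    windows = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n) * width,
            "end": (np.arange(n) + 1) * width,
        }
    )
    return WindowCounts(windows, context, mc_a, cov_a, mc_b, cov_b)


class TestCallDmrs:
    def test_clear_difference_called_with_direction(self):
        counts = _counts_from_arrays(
            mc_a=[[1], [2]], cov_a=[[50], [50]], mc_b=[[20], [22]], cov_b=[[50], [50]]
        )
        dmrs = rm.call_dmrs(counts)
        assert len(dmrs) == 1
        assert dmrs["direction"].iloc[0] == "hypo"
        assert dmrs["difference"].iloc[0] < -0.1

    def test_inconsistent_replicate_pairing_rejected(self):
        """A window where one A-replicate x B-replicate pairing differs by
        only 0.05 fails the consistency filter even though the pooled
        difference clears the CHH threshold."""
        # A1=0.00, A2=0.10, B=0.16: pooled diff -0.11 clears the threshold
        # but the A2-B pairings differ by only 0.06
        counts = _counts_from_arrays(
            mc_a=[[0], [10]], cov_a=[[100], [100]], mc_b=[[16], [16]], cov_b=[[100], [100]]
        )
        assert len(rm.call_dmrs(counts)) == 0

    def test_zero_coverage_pairing_is_conservative(self):
        counts = _counts_from_arrays(
            mc_a=[[0], [0]], cov_a=[[50], [0]], mc_b=[[20], [20]], cov_b=[[25], [25]]
        )
        assert len(rm.call_dmrs(counts)) == 0

    def test_informative_filter_per_sample_vs_joint(self):
        counts = _counts_from_arrays(
            mc_a=[[0], [0]], cov_a=[[8], [8]], mc_b=[[10], [10]], cov_b=[[12], [12]]
        )
        assert len(rm.call_dmrs(counts, informative_rule="per_sample")) == 0
        assert len(rm.call_dmrs(counts, informative_rule="joint")) == 1

    def test_direction_antisymmetry(self, small_fixture):
        """hypo DMRs of A-vs-B are exactly the hyper DMRs of B-vs-A, with
        identical p-values."""
        annotation, tracks, _, _ = small_fixture
        fwd = rm.call_dmrs(
            rm.window_counts(tracks[2:4], tracks[:2], annotation.chrom_lengths, "CHH")
        )
        rev = rm.call_dmrs(
            rm.window_counts(tracks[:2], tracks[2:4], annotation.chrom_lengths, "CHH")
        )
        f_hypo = fwd[fwd["direction"] == "hypo"].set_index(["chrom", "start"])
        r_hyper = rev[rev["direction"] == "hyper"].set_index(["chrom", "start"])
        assert set(f_hypo.index) == set(r_hyper.index)
        assert np.allclose(
            f_hypo["p_value"].sort_index(), r_hyper["p_value"].sort_index()
        )

    def test_null_simulation_rare_false_calls(self):
        """With equal proportions the conjunction of filters calls far fewer
        windows than alpha alone would."""
        config = rm.SimulationConfig(
            n_genes=10, n_tes=20, chrom_length=500_000, planted_dmr_count=0, seed=21
        )
        annotation, tracks, _, _ = rm.simulate_all(config)
        counts = rm.window_counts(
            tracks[2:4], tracks[:2], annotation.chrom_lengths, "CHH"
        )
        dmrs = rm.call_dmrs(counts)
        assert len(dmrs) / len(counts.windows) <= 0.005


class TestAnnotateDmrs:
    @staticmethod
    def _annotation():
        genes = pd.DataFrame(
            [("chr1", 10_000, 12_000, "g1", "+")],
            columns=["chrom", "start", "end", "name", "strand"],
        )
        tes = pd.DataFrame(
            [("chr1", 8_500, 8_800, "te1", "+")],
            columns=["chrom", "start", "end", "name", "strand"],
        )
        return rm.GenomeAnnotation({"chr1": 50_000}, genes, tes)

    def _dmrs(self, coords):
        return pd.DataFrame(
            [("chr1", s, e, "CHH", -0.2, 1e-4, "hypo") for s, e in coords],
            columns=["chrom", "start", "end", "context", "difference", "p_value", "direction"],
        )

    def test_precedence_te_over_promoter(self):
        # the TE at 8500-8800 lies inside g1's promoter (8000-10000)
        out = rm.annotate_dmrs(self._dmrs([(8_600, 8_650)]), self._annotation())
        assert out["feature"].iloc[0] == "TE"

    def test_promoter_gene_intergenic(self):
        out = rm.annotate_dmrs(
            self._dmrs([(9_000, 9_050), (11_000, 11_050), (30_000, 30_050)]),
            self._annotation(),
        )
        assert list(out["feature"]) == ["promoter", "gene", "intergenic"]

    def test_categories_partition_dmrs(self, small_fixture):
        annotation, tracks, _, _ = small_fixture
        dmrs = rm.call_dmrs(
            rm.window_counts(tracks[2:4], tracks[:2], annotation.chrom_lengths, "CHH")
        )
        out = rm.annotate_dmrs(dmrs, annotation)
        summary = summarize_dmrs(out)
        assert summary["count"].sum() == len(dmrs)


class TestOverlapSets:
    def test_disjoint_and_identical(self):
        a = pd.DataFrame([("chr1", 0, 50)], columns=["chrom", "start", "end"])
        b = pd.DataFrame([("chr1", 50, 100)], columns=["chrom", "start", "end"])
        counts = rm.overlap_dmr_sets({"A": a, "B": b})
        assert counts[frozenset({"A", "B"})] == 0
        counts = rm.overlap_dmr_sets({"A": a, "B": a})
        assert counts[frozenset({"A", "B"})] == 1
        assert counts[frozenset({"A"})] == 0

    def test_three_sets_match_brute_force(self):
        rng = np.random.default_rng(5)
        universe = [("chr1", i * 50, (i + 1) * 50) for i in range(40)]
        sets = {
            name: {w for w in universe if rng.random() < 0.4} for name in "XYZ"
        }
        got = venn_counts(sets)
        for inside_mask in itertools.product([0, 1], repeat=3):
            if not any(inside_mask):
                continue
            inside = {n for n, m in zip("XYZ", inside_mask) if m}
            expected = sum(
                1
                for w in universe
                if all((w in sets[n]) == (n in inside) for n in "XYZ")
            )
            assert got[frozenset(inside)] == expected
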