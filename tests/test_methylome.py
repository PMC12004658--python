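"""Weighted levels, binning, percent change, metaplots and replicate QC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rootmeth as rm
from rootmeth.errors import InsufficientDataError, ParseError, ValidationError
from rootmeth.methylome import (
    describe_percent_change,
    methylation_by_bin,
    pool_sites,
    write_cytosine_report,
)

from conftest import make_track


class TestWeightedMethylation:
    def test_basic_arithmetic(self):
        track = make_track([("chr1", 10, "+", "CHH", 5, 100)])
        assert rm.weighted_methylation(track, "CHH").level == 0.05

    def test_pooled_not_averaged(self):
        """Two replicates (3/10) and (1/30) pool to 4/40 = 0.1, not the
        mean of the per-replicate levels."""
        r1 = make_track([("chr1", 10, "+", "CHH", 3, 10)], replicate="R1")
        r2 = make_track([("chr1", 10, "+", "CHH", 1, 30)], replicate="R2")
        s = rm.weighted_methylation([r1, r2], "CHH")
        assert s.level == pytest.approx(0.1)
        assert (s.mc_total, s.cov_total) == (4, 40)

    def test_all_unmethylated(self):
        track = make_track([("chr1", p, "+", "CG", 0, 5) for p in (1, 2, 3)])
        assert rm.weighted_methylation(track, "CG").level == 0.0

    def test_zero_coverage_flagged_not_raised(self):
        track = make_track([("chr1", 1, "+", "CG", 0, 5)])
        s = rm.weighted_methylation(track, "CHH")
        assert not s.defined
        assert np.isnan(s.level)

    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50)), min_size=1, max_size=30),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_order_and_split_invariance(self, counts, rnd):
        """Pooling is invariant to site order and to how sites are split
        into replicates before pooling."""
        rows = [
            ("chr1", i + 1, "+", "CHH", min(mc, cov), cov)
            for i, (mc, cov) in enumerate(counts)
        ]
        whole = rm.weighted_methylation(make_track(rows), "CHH")
        shuffled = rows[:]
        rnd.shuffle(shuffled)
        cut = rnd.randrange(len(rows) + 1)
        split = [make_track(shuffled[:cut]), make_track(shuffled[cut:])]
        parts = rm.weighted_methylation(split, "CHH")
        assert (whole.mc_total, whole.cov_total) == (parts.mc_total, parts.cov_total)


class TestReportParsing:
    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("#chrom\tpos\tstrand\tcontext\tmc\tcov\nchr1\t5\t+\tCHH\t1\t2\nchr1\tx\t+\tCHH\t1\t2\n")
        with pytest.raises(ParseError, match="line 3"):
            rm.read_cytosine_report(p)

    def test_mc_greater_than_cov_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chr1\t5\t+\tCHH\t7\t5\n")
        with pytest.raises(ValidationError):
            rm.read_cytosine_report(p)

    def test_round_trip(self, tmp_path):
        track = make_track(
            [("chr1", 3, "+", "CG", 1, 4), ("chr1", 3, "-", "CHH", 0, 2), ("chr2", 1, "+", "CHG", 2, 2)]
        )
        path = tmp_path / "t.tsv"
        write_cytosine_report(track, path)
        back = rm.read_cytosine_report(path)
        pd.testing.assert_frame_equal(back.sites, track.sites)

    def test_gzip_input(self, tmp_path):
        import gzip

        p = tmp_path / "t.tsv.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("chr1\t5\t+\tCHH\t1\t2\n")
        assert len(rm.read_cytosine_report(p)) == 1


class TestPercentChange:
    @pytest.mark.parametrize(
        "before,after,expected,direction",
        [
            (5.02, 3.31, 34.06, "decrease"),
            (2.44, 3.13, 28.28, "increase"),
            (3.37, 1.86, 44.81, "decrease"),
        ],
    )
    def test_reported_stage_changes(self, before, after, expected, direction):
        magnitude, d = describe_percent_change(before, after)
        assert round(magnitude, 2) == expected
        assert d == direction

    def test_identity(self):
        assert rm.percent_change(0.05, 0.05) == 0.0

    def test_zero_before_undefined(self):
        with pytest.raises(ValueError):
            rm.percent_change(0.0, 0.1)

    @given(st.floats(0.001, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_sign_matches_direction(self, before, after):
        pc = rm.percent_change(before, after)
        if after < before:
            assert pc > 0
        elif after > before:
            assert pc < 0
        else:
            assert pc == 0


class TestCoverageEstimate:
    def test_printed_formula(self):
        assert rm.estimate_coverage(17e6, 17e6) == pytest.approx(34e6 * 300 / 373e6)

    def test_zero(self):
        assert rm.estimate_coverage(0, 0) == 0.0

    def test_linearity(self):
        full = rm.estimate_coverage(12e6, 18e6)
        half = rm.estimate_coverage(6e6, 9e6)
        assert full == pytest.approx(2 * half)


class TestBinnedMethylation:
    def test_partial_final_bin(self):
        track = make_track(
            [("chr1", 1, "+", "CHH", 1, 2), ("chr1", 150_001, "+", "CHH", 1, 2), ("chr1", 240_000, "+", "CHH", 0, 2)]
        )
        bins = rm.methylation_by_100kb(track, "CHH", {"chr1": 250_000})
        assert list(bins["start"]) == [0, 100_000, 200_000]
        assert bins["end"].iloc[-1] == 250_000

    def test_empty_bins_excluded(self):
        track = make_track([("chr1", 5, "+", "CHH", 1, 2)])
        bins = rm.methylation_by_100kb(track, "CHH", {"chr1": 300_000})
        assert len(bins) == 1

    def test_uniform_simulation_centered_at_baseline(self, small_config, small_fixture):
        _, tracks, _, _ = small_fixture
        bins = rm.methylation_by_100kb(tracks[:2], "CHH", {"chr1": small_config.chrom_length})
        assert bins["level"].median() == pytest.approx(
            small_config.baseline_methylation[2], abs=0.01
        )


class TestMetaplot:
    @staticmethod
    def _features(strands=("+", "-")):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [1000, 5000],
                "end": [2000, 6500],
                "name": ["a", "b"],
                "strand": list(strands),
            }
        )

    @staticmethod
    def _uniform_track(level=0.2, cov=10):
        rows = [
            ("chr1", p, "+", "CHH", int(level * cov), cov) for p in range(1, 9001, 7)
        ]
        return make_track(rows)

    def test_uniform_methylation_gives_flat_profile(self):
        prof = rm.metaplot(self._uniform_track(), self._features(), "CHH", flank=500)
        levels = prof["level"].dropna()
        assert levels.nunique() == 1
        assert levels.iloc[0] == pytest.approx(0.2)

    def test_count_conservation(self):
        """Summed bin counts equal the counts over all feature+flank sites
        (features here non-overlapping, flanks disjoint)."""
        track = self._uniform_track()
        feats = self._features()
        flank = 500
        prof = rm.metaplot(track, feats, "CHH", flank=flank)
        expected_mc = expected_cov = 0
        for f in feats.itertuples(index=False):
            sub = track.sites[
                (track.sites["pos"] - 1 >= f.start - flank)
                & (track.sites["pos"] - 1 < f.end + flank)
            ]
            expected_mc += sub["mc"].sum()
            expected_cov += sub["cov"].sum()
        assert prof["mc"].sum() == expected_mc
        assert prof["cov"].sum() == expected_cov

    def test_strand_flip_reverses_profile(self):
        """Flipping every feature's strand mirrors the profile 5'->3'."""
        rng = np.random.default_rng(0)
        rows = [
            ("chr1", p, "+", "CHH", int(rng.integers(0, 5)), 10)
            for p in range(1, 9001, 11)
        ]
        track = make_track(rows)
        fwd = rm.metaplot(track, self._features(("+", "+")), "CHH", flank=500)
        rev = rm.metaplot(track, self._features(("-", "-")), "CHH", flank=500)
        assert list(fwd["mc"]) == list(rev["mc"][::-1])
        assert list(fwd["cov"]) == list(rev["cov"][::-1])

    def test_planted_te_body_enrichment_recovered(self, small_fixture):
        """TEs carrying planted windows show elevated CHH in their bodies
        relative to flanks in the high-methylation (S0) sample."""
        annotation, tracks, _, truth = small_fixture
        planted = truth.planted_windows
        hits = []
        for te in annotation.tes.itertuples(index=False):
            inside = (
                (planted["chrom"] == te.chrom)
                & (planted["start"] >= te.start)
                & (planted["end"] <= te.end)
            )
            if inside.any():
                hits.append(te)
        feats = pd.DataFrame(hits)
        prof = rm.metaplot(tracks[0], feats, "CHH", flank=1000)
        body = prof.loc[prof["region"] == "body", "level"].mean()
        flank = prof.loc[prof["region"] != "body", "level"].mean()
        assert body > flank


class TestReplicateCorrelation:
    def test_identical_replicates(self, small_fixture):
        _, tracks, _, _ = small_fixture
        r = rm.replicate_correlation(tracks[0], tracks[0], "CHH", {"chr1": 200_000}, 10_000)
        assert r == pytest.approx(1.0)

    def test_same_expectation_deep_coverage(self):
        """Two replicates sharing site-specific methylation proportions but
        with independent 30x count noise correlate above 0.9 at the bin
        level (genuine across-genome variance dominates sampling noise)."""
        rng = np.random.default_rng(6)
        n_sites = 20_000
        pos = np.arange(1, n_sites * 20, 20)
        # regional heterogeneity: proportions drift slowly along the genome
        p_site = 0.5 * (1 + np.sin(pos / 30_000)) * rng.beta(5, 5, size=n_sites)
        tracks = []
        for rep in ("R1", "R2"):
            cov = rng.poisson(30, size=n_sites)
            mc = rng.binomial(cov, p_site)
            keep = cov > 0
            tracks.append(
                make_track(
                    list(zip(
                        ["chr1"] * int(keep.sum()), pos[keep], ["+"] * int(keep.sum()),
                        ["CHH"] * int(keep.sum()), mc[keep], cov[keep],
                    )),
                    replicate=rep,
                )
            )
        r = rm.replicate_correlation(
            tracks[0], tracks[1], "CHH", {"chr1": int(pos[-1]) + 1}, 5_000
        )
        assert r > 0.9

    def test_independent_tracks_uncorrelated(self):
        rng = np.random.default_rng(12)
        n = 1200
        def rand_track(seed_rng):
            rows = [
                ("chr1", 1 + i * 100, "+", "CHH", int(seed_rng.integers(0, 11)), 10)
                for i in range(n)
            ]
            return make_track(rows)
        r = rm.replicate_correlation(
            rand_track(rng), rand_track(rng), "CHH", {"chr1": n * 100 + 10}, 100
        )
        assert abs(r) < 0.1

    def test_insufficient_shared_bins(self):
        t1 = make_track([("chr1", 5, "+", "CHH", 1, 2)])
        t2 = make_track([("chr1", 5, "+", "CHH", 1, 2)])
        with pytest.raises(InsufficientDataError):
            rm.replicate_correlation(t1, t2, "CHH", {"chr1": 100}, 50)
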