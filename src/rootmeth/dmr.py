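"""Windowed differential-methylation calling.

The genome is tiled into 50-bp windows; per window and context, methylated
and total counts are summed per replicate for the two samples being
compared.  A window is a DMR when it clears four conjunctive filters:

1. coverage — at least ``min_informative`` summed cytosine depth (the two
   replicates together) in *each* sample;
2. effect size — the pooled level difference exceeds the per-context
   threshold (0.5 CG / 0.3 CHG / 0.1 CHH);
3. significance — two-sided Fisher exact p on the pooled 2×2 count table
   below ``alpha`` (0.05);
4. replicate consistency — every cross pairing of an A replicate with a B
   replicate shows a difference of the same sign exceeding the threshold.

Direction is *hypo* when sample A (the later stage in a "stage 1 versus
stage 0" comparison) is less methylated than sample B, *hyper* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .methylome import MethylomeTrack
from .synthetic import GenomeAnnotation

CONTEXT_THRESHOLDS = {"CG": 0.5, "CHG": 0.3, "CHH": 0.1}
WINDOW_WIDTH = 50
MIN_INFORMATIVE = 20
ALPHA = 0.05
FEATURE_PRECEDENCE = ("TE", "promoter", "gene", "intergenic")


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def partition_windows(chrom_lengths: dict[str, int], width: int = WINDOW_WIDTH) -> pd.DataFrame:
    """Disjoint tiling of each chromosome into fixed-width windows.

    0-based half-open; the last window of a chromosome may be short.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    rows = []
    for chrom, length in chrom_lengths.items():
        if length < 1:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        starts = np.arange(0, length, width)
        ends = np.minimum(starts + width, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


@dataclass
class WindowCounts:
    """Per-window, per-replicate counts for one two-sample comparison."""

    windows: pd.DataFrame  # chrom, start, end
    context: str
    mc_a: np.ndarray  # (n_replicates_a, n_windows)
    cov_a: np.ndarray
    mc_b: np.ndarray
    cov_b: np.ndarray

    @property
    def informative_a(self) -> np.ndarray:
        """Summed sequenced depth over both A replicates, per window."""
        return self.cov_a.sum(axis=0)

    @property
    def informative_b(self) -> np.ndarray:
        return self.cov_b.sum(axis=0)

    def pooled_levels(self) -> tuple[np.ndarray, np.ndarray]:
        """(m_A, m_B) weighted levels; NaN where a sample has no coverage."""
        with np.errstate(invalid="ignore", divide="ignore"):
            m_a = self.mc_a.sum(axis=0) / self.informative_a
            m_b = self.mc_b.sum(axis=0) / self.informative_b
        return m_a, m_b


def _bin_track(
    track: MethylomeTrack,
    context: str,
    offsets: dict[str, int],
    width: int,
    n_windows: int,
) -> tuple[np.ndarray, np.ndarray]:
    sub = track.subset(context)
    mc = np.zeros(n_windows, dtype=np.int64)
    cov = np.zeros(n_windows, dtype=np.int64)
    for chrom, cdf in sub.groupby("chrom"):
        if chrom not in offsets:
            continue
        idx = offsets[chrom] + (cdf["pos"].to_numpy() - 1) // width
        np.add.at(mc, idx, cdf["mc"].to_numpy())
        np.add.at(cov, idx, cdf["cov"].to_numpy())
    return mc, cov


def window_counts(
    tracks_a: list[MethylomeTrack],
    tracks_b: list[MethylomeTrack],
    chrom_lengths: dict[str, int],
    context: str,
    width: int = WINDOW_WIDTH,
) -> WindowCounts:
    """Sum per-replicate (mc, cov) over window tiles for both samples.

    Sites of both strands contribute to the window containing their 0-based
    position (half-open boundaries).
    """
    windows = partition_windows(chrom_lengths, width)
    offsets: dict[str, int] = {}
    off = 0
    for chrom, length in chrom_lengths.items():
        offsets[chrom] = off
        off += -(-length // width)
    n = len(windows)

    def stack(tracks):
        mcs, covs = [], []
        for t in tracks:
            mc, cov = _bin_track(t, context, offsets, width, n)
            mcs.append(mc)
            covs.append(cov)
        return np.vstack(mcs), np.vstack(covs)

    mc_a, cov_a = stack(tracks_a)
    mc_b, cov_b = stack(tracks_b)
    return WindowCounts(windows, context, mc_a, cov_a, mc_b, cov_b)


# ---------------------------------------------------------------------------
# Fisher's exact test (two-sided, exact integer arithmetic)
# ---------------------------------------------------------------------------

def fisher_exact_test(mc_a: int, cov_a: int, mc_b: int, cov_b: int) -> float:
    """Two-sided Fisher exact p for [[mc_a, cov_a−mc_a], [mc_b, cov_b−mc_b]].

    Uses the standard rule — sum the probabilities of all tables with the
    observed margins whose probability does not exceed the observed table's.
    Table selection compares exact integer hypergeometric numerators, so tie
    handling is exact; the only floating-point step is the final division.
    Degenerate margins give p = 1.
    """
    for v in (mc_a, cov_a, mc_b, cov_b):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if mc_a > cov_a or mc_b > cov_b:
        raise ValueError("mc cannot exceed cov")
    n = cov_a + cov_b
    c1 = mc_a + mc_b
    if n == 0 or c1 == 0 or c1 == n:
        return 1.0
    kmin = max(0, c1 - cov_b)
    kmax = min(cov_a, c1)
    n_obs = comb(cov_a, mc_a) * comb(cov_b, c1 - mc_a)
    acc = 0
    for k in range(kmin, kmax + 1):
        nk = comb(cov_a, k) * comb(cov_b, c1 - k)
        if nk <= n_obs:
            acc += nk
    return acc / comb(n, c1)


# ---------------------------------------------------------------------------
# DMR calling
# ---------------------------------------------------------------------------

def call_dmrs(
    counts: WindowCounts,
    min_informative: int = MIN_INFORMATIVE,
    thresholds: dict[str, float] = CONTEXT_THRESHOLDS,
    alpha: float = ALPHA,
    informative_rule: str = "per_sample",
) -> pd.DataFrame:
    """Apply the four DMR filters to a :class:`WindowCounts` comparison.

    ``informative_rule`` is "per_sample" (each sample needs
    ``min_informative`` depth) or "joint" (the two samples together do).
    Returns a frame with chrom, start, end, context, m_a, m_b, difference
    (m_a − m_b), p_value and direction.
    """
    threshold = thresholds[counts.context]
    m_a, m_b = counts.pooled_levels()
    info_a, info_b = counts.informative_a, counts.informative_b
    if informative_rule == "per_sample":
        informative = (info_a >= min_informative) & (info_b >= min_informative)
    elif informative_rule == "joint":
        informative = (info_a + info_b) >= min_informative
    else:
        raise ValueError(f"unknown informative_rule {informative_rule!r}")
    informative &= (info_a > 0) & (info_b > 0)

    diff = m_a - m_b
    with np.errstate(invalid="ignore"):
        candidate = informative & (np.abs(diff) > threshold)

    # replicate-consistency: every A-replicate × B-replicate pairing must
    # show a same-sign difference above the threshold; a pairing with zero
    # coverage on either side fails the window
    with np.errstate(invalid="ignore", divide="ignore"):
        lv_a = counts.mc_a / counts.cov_a
        lv_b = counts.mc_b / counts.cov_b
    pair_diff = lv_a[:, None, :] - lv_b[None, :, :]  # (ra, rb, W)
    sign = np.sign(diff)
    consistent = np.all(
        np.isfinite(pair_diff)
        & (np.abs(pair_diff) > threshold)
        & (np.sign(pair_diff) == sign),
        axis=(0, 1),
    )
    candidate &= consistent

    rows = []
    mc_a_tot = counts.mc_a.sum(axis=0)
    mc_b_tot = counts.mc_b.sum(axis=0)
    win = counts.windows
    for i in np.flatnonzero(candidate):
        p = fisher_exact_test(
            int(mc_a_tot[i]), int(info_a[i]), int(mc_b_tot[i]), int(info_b[i])
        )
        if p < alpha:
            rows.append(
                (
                    win.iat[i, 0],
                    int(win.iat[i, 1]),
                    int(win.iat[i, 2]),
                    counts.context,
                    float(m_a[i]),
                    float(m_b[i]),
                    float(diff[i]),
                    p,
                    "hypo" if diff[i] < 0 else "hyper",
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "context",
            "m_a",
            "m_b",
            "difference",
            "p_value",
            "direction",
        ],
    )


# ---------------------------------------------------------------------------
# genomic annotation of DMRs
# ---------------------------------------------------------------------------

def _build_trees(frame: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in frame.itertuples(index=False):
        if row.end > row.start:
            trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    return trees


def annotate_dmrs(
    dmrs: pd.DataFrame,
    annotation: GenomeAnnotation,
    promoter_span: int = 2000,
) -> pd.DataFrame:
    """Assign each DMR one feature category by precedence
    TE > promoter > gene body > intergenic, using any-overlap."""
    layers = [
        ("TE", _build_trees(annotation.tes)),
        ("promoter", _build_trees(annotation.promoters(promoter_span))),
        ("gene", _build_trees(annotation.genes)),
    ]
    features = []
    for row in dmrs.itertuples(index=False):
        assigned = "intergenic"
        for name, trees in layers:
            tree = trees.get(row.chrom)
            if tree is not None and tree.overlap(row.start, row.end):
                assigned = name
                break
        features.append(assigned)
    out = dmrs.copy()
    out["feature"] = features
    return out


def summarize_dmrs(annotated: pd.DataFrame) -> pd.DataFrame:
    """Counts per direction × feature (the layout of the DMR histograms)."""
    if len(annotated) == 0:
        return pd.DataFrame(columns=["direction", "feature", "count"])
    out = (
        annotated.groupby(["direction", "feature"], observed=True)
        .size()
        .reset_index(name="count")
    )
    return out


# ---------------------------------------------------------------------------
# overlap of DMR sets
# ---------------------------------------------------------------------------

def _window_keys(dmrs: pd.DataFrame) -> set[tuple]:
    return {(r.chrom, int(r.start), int(r.end)) for r in dmrs.itertuples(index=False)}


def venn_counts(sets: dict[str, set]) -> dict[frozenset, int]:
    """Exclusive region counts of the Venn partition over named sets."""
    names = list(sets)
    out: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for inside in combinations(names, r):
            region = set.intersection(*(sets[n] for n in inside))
            for n in names:
                if n not in inside:
                    region -= sets[n]
            out[frozenset(inside)] = len(region)
    return out


def overlap_dmr_sets(named_dmrs: dict[str, pd.DataFrame]) -> dict[frozenset, int]:
    """Venn-partition counts of DMR windows (identified by coordinates)."""
    return venn_counts({name: _window_keys(df) for name, df in named_dmrs.items()})


def write_dmr_bed(annotated: pd.DataFrame, path) -> None:
    """BED-like DMR table; coordinates 1-based inclusive in the output."""
    out = annotated.copy()
    out["start"] = out["start"] + 1  # 1-based inclusive
    cols = ["chrom", "start", "end", "context", "difference", "p_value", "direction"]
    if "feature" in out.columns:
        cols.append("feature")
    out[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")
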