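"""Association of DMRs with (short) transposable elements.

Two analyses: the length distribution of TEs overlapped by DMR windows
versus TEs overlapped by randomly placed control windows (2000 per
chromosome by default), and the positional density of short TEs (< 500 bp)
across scaled genic regions and their flanks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .errors import ConfigError, InsufficientDataError

N_CONTROL_PER_CHROM = 2000
CONTROL_WIDTH = 50
SHORT_TE_CUTOFF = 500


# ---------------------------------------------------------------------------
# control windows
# ---------------------------------------------------------------------------

def sample_control_windows(
    chrom_lengths: dict[str, int],
    n_per_chromosome: int = N_CONTROL_PER_CHROM,
    width: int = CONTROL_WIDTH,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Uniformly random fixed-width windows, ``n_per_chromosome`` each.

    Start positions are drawn with replacement, so control windows may
    overlap one another; every window lies fully inside its chromosome.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for chrom, length in chrom_lengths.items():
        if length < width:
            raise ConfigError(f"chromosome {chrom} shorter than window width {width}")
        starts = rng.integers(0, length - width + 1, size=n_per_chromosome)
        starts = np.sort(starts)
        rows.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + width})
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# window-associated TE lengths
# ---------------------------------------------------------------------------

def associated_te_lengths(
    windows: pd.DataFrame, tes: pd.DataFrame, distinct: bool = False
) -> np.ndarray:
    """Lengths of TEs overlapped by the given windows.

    By default a TE overlapped by k windows contributes k entries (the unit
    of observation is the window–TE overlap event); ``distinct=True`` counts
    each TE once.
    """
    trees: dict[str, IntervalTree] = {}
    for i, row in enumerate(tes.itertuples(index=False)):
        if row.end > row.start:
            trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, i)
    lengths: list[int] = []
    seen: set[int] = set()
    for row in windows.itertuples(index=False):
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(row.start, row.end):
            if distinct:
                if iv.data in seen:
                    continue
                seen.add(iv.data)
            lengths.append(iv.end - iv.begin)
    return np.asarray(sorted(lengths), dtype=np.int64)


@dataclass(frozen=True)
class TELengthComparison:
    """Summary of DMR-associated versus control-associated TE lengths."""

    dmr_n: int
    control_n: int
    dmr_median: float
    control_median: float
    dmr_quartiles: tuple[float, float]
    control_quartiles: tuple[float, float]
    dmr_short_fraction: float
    control_short_fraction: float
    statistic: float
    p_value: float


def compare_length_distributions(
    dmr_lengths: np.ndarray,
    control_lengths: np.ndarray,
    short_cutoff: int = SHORT_TE_CUTOFF,
) -> TELengthComparison:
    """Rank-based (Mann–Whitney U) two-sample comparison of TE lengths."""
    dmr_lengths = np.asarray(dmr_lengths)
    control_lengths = np.asarray(control_lengths)
    if len(dmr_lengths) == 0 or len(control_lengths) == 0:
        raise InsufficientDataError("both length groups must be non-empty")
    stat, p = stats.mannwhitneyu(dmr_lengths, control_lengths, alternative="two-sided")
    q1d, q3d = np.percentile(dmr_lengths, [25, 75])
    q1c, q3c = np.percentile(control_lengths, [25, 75])
    return TELengthComparison(
        dmr_n=len(dmr_lengths),
        control_n=len(control_lengths),
        dmr_median=float(np.median(dmr_lengths)),
        control_median=float(np.median(control_lengths)),
        dmr_quartiles=(float(q1d), float(q3d)),
        control_quartiles=(float(q1c), float(q3c)),
        dmr_short_fraction=float(np.mean(dmr_lengths < short_cutoff)),
        control_short_fraction=float(np.mean(control_lengths < short_cutoff)),
        statistic=float(stat),
        p_value=float(p),
    )


# ---------------------------------------------------------------------------
# short-TE positional profile over genic regions
# ---------------------------------------------------------------------------

def short_te_genic_profile(
    tes: pd.DataFrame,
    genes: pd.DataFrame,
    length_cutoff: int = SHORT_TE_CUTOFF,
    flank: int = 2000,
    n_body_bins: int = 20,
    n_flank_bins: int = 10,
) -> pd.DataFrame:
    """Density of short-TE midpoints per scaled genic/flank bin.

    Midpoints are assigned to bins as in the methylation metaplot
    (strand-aware, minus-strand genes reversed); counts are normalised by
    the total bp each bin represents across genes, giving midpoints per bp.
    """
    if len(genes) == 0:
        raise ValueError("need at least one gene")
    short = tes[(tes["end"] - tes["start"]) < length_cutoff]
    mids = short["start"].to_numpy() + (short["end"].to_numpy() - short["start"].to_numpy()) // 2
    mid_by_chrom = {
        chrom: np.sort(mids[(short["chrom"] == chrom).to_numpy()])
        for chrom in short["chrom"].unique()
    }
    n_total = 2 * n_flank_bins + n_body_bins
    counts = np.zeros(n_total)
    bp = np.zeros(n_total)
    for gene in genes.itertuples(index=False):
        start, end = int(gene.start), int(gene.end)
        width = end - start
        # bp represented by each bin for this gene
        gene_bp = np.concatenate(
            [
                np.full(n_flank_bins, flank / n_flank_bins),
                np.full(n_body_bins, width / n_body_bins),
                np.full(n_flank_bins, flank / n_flank_bins),
            ]
        )
        bp += gene_bp[::-1] if gene.strand == "-" else gene_bp
        pos = mid_by_chrom.get(gene.chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, start - flank, side="left")
        hi = np.searchsorted(pos, end + flank, side="left")
        if lo == hi:
            continue
        p = pos[lo:hi]
        idx = np.empty(len(p), dtype=np.int64)
        up = p < start
        down = p >= end
        body = ~up & ~down
        idx[up] = np.minimum(((p[up] - (start - flank)) * n_flank_bins) // flank, n_flank_bins - 1)
        idx[down] = (
            n_flank_bins
            + n_body_bins
            + np.minimum(((p[down] - end) * n_flank_bins) // flank, n_flank_bins - 1)
        )
        idx[body] = n_flank_bins + np.minimum(((p[body] - start) * n_body_bins) // width, n_body_bins - 1)
        if gene.strand == "-":
            idx = n_total - 1 - idx
        np.add.at(counts, idx, 1)
    region = ["upstream"] * n_flank_bins + ["body"] * n_body_bins + ["downstream"] * n_flank_bins
    with np.errstate(invalid="ignore", divide="ignore"):
        density = np.where(bp > 0, counts / np.maximum(bp, 1e-300), 0.0)
    return pd.DataFrame(
        {"bin": np.arange(n_total), "region": region, "count": counts.astype(np.int64), "density": density}
    )
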