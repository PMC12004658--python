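"""Per-cytosine methylation tracks and genome-wide summaries.

The central currency of the pipeline is the *cytosine report*: one row per
sequenced cytosine with its chromosome, 1-based position, strand, sequence
context (CG, CHG or CHH — H is A, C or T), methylated-read count and total
read coverage.  All summaries here use the *weighted* methylation level,
i.e. summed methylated counts divided by summed coverage, pooling sites and
replicates by counts rather than averaging per-site ratios.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ParseError, ValidationError

CONTEXTS = ("CG", "CHG", "CHH")
STRANDS = ("+", "-")

SITE_COLUMNS = ["chrom", "pos", "strand", "context", "mc", "cov"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MethylomeTrack:
    """One BS-seq library: every covered cytosine of one sample-replicate.

    ``sites`` is a DataFrame with columns chrom, pos (1-based), strand,
    context, mc, cov, sorted by (chrom, pos, strand) with no duplicate keys.
    """

    sample: str
    replicate: str
    sites: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.sites
        missing = [c for c in SITE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"track missing columns: {missing}")
        if len(df) and (df["mc"] > df["cov"]).any():
            bad = int(np.argmax((df["mc"] > df["cov"]).to_numpy()))
            raise ValidationError(f"mc > cov at row {bad}")
        df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort")
        if df.duplicated(["chrom", "pos", "strand"]).any():
            raise ValidationError("duplicate (chrom, pos, strand) site")
        self.sites = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.sites)

    def subset(self, context: str) -> pd.DataFrame:
        return self.sites[self.sites["context"] == context]


@dataclass(frozen=True)
class MethylationSummary:
    """Pooled weighted methylation level for one context over some region."""

    context: str
    mc_total: int
    cov_total: int

    @property
    def defined(self) -> bool:
        return self.cov_total > 0

    @property
    def level(self) -> float:
        """Weighted level Σmc/Σcov; NaN when no coverage."""
        if self.cov_total == 0:
            return float("nan")
        return self.mc_total / self.cov_total


# ---------------------------------------------------------------------------
# cytosine-report I/O
# ---------------------------------------------------------------------------

REPORT_HEADER = "#chrom\tpos\tstrand\tcontext\tmc\tcov"


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_cytosine_report(path, sample: str = "", replicate: str = "") -> MethylomeTrack:
    """Parse a tab-separated cytosine report into a :class:`MethylomeTrack`.

    Malformed rows raise :class:`ParseError` with the 1-based file line
    number; rows with mc > cov raise :class:`ValidationError`.
    """
    chroms: list[str] = []
    poss: list[int] = []
    strands: list[str] = []
    contexts: list[str] = []
    mcs: list[int] = []
    covs: list[int] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError(f"expected 6 columns, got {len(parts)}", lineno)
            chrom, pos_s, strand, context, mc_s, cov_s = parts
            try:
                pos, mc, cov = int(pos_s), int(mc_s), int(cov_s)
            except ValueError:
                raise ParseError(f"non-integer field in {parts!r}", lineno) from None
            if strand not in STRANDS:
                raise ParseError(f"bad strand {strand!r}", lineno)
            if context not in CONTEXTS:
                raise ParseError(f"bad context {context!r}", lineno)
            if pos < 1 or mc < 0 or cov < 0:
                raise ParseError("negative count or position < 1", lineno)
            if mc > cov:
                raise ValidationError(f"line {lineno}: mc={mc} > cov={cov}")
            chroms.append(chrom)
            poss.append(pos)
            strands.append(strand)
            contexts.append(context)
            mcs.append(mc)
            covs.append(cov)
    df = pd.DataFrame(
        {
            "chrom": pd.array(chroms, dtype=str),
            "pos": np.asarray(poss, dtype=np.int64),
            "strand": pd.array(strands, dtype=str),
            "context": pd.array(contexts, dtype=str),
            "mc": np.asarray(mcs, dtype=np.int64),
            "cov": np.asarray(covs, dtype=np.int64),
        }
    )
    return MethylomeTrack(sample=sample, replicate=replicate, sites=df)


def write_cytosine_report(track: MethylomeTrack, path) -> None:
    """Write a track in the report dialect read by :func:`read_cytosine_report`."""
    with _open_text(path, "wt") as fh:
        fh.write(REPORT_HEADER + "\n")
        for row in track.sites.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.strand}\t{row.context}\t{row.mc}\t{row.cov}\n"
            )


# ---------------------------------------------------------------------------
# pooling helpers
# ---------------------------------------------------------------------------

def _as_site_frames(sites) -> list[pd.DataFrame]:
    if isinstance(sites, MethylomeTrack):
        return [sites.sites]
    if isinstance(sites, pd.DataFrame):
        return [sites]
    frames = []
    for item in sites:
        frames.extend(_as_site_frames(item))
    return frames


def pool_sites(sites) -> pd.DataFrame:
    """Concatenate any mix of tracks / site frames into one site frame."""
    frames = _as_site_frames(sites)
    if len(frames) == 1:
        return frames[0]
    return pd.concat(frames, ignore_index=True)


def weighted_methylation(sites, context: str) -> MethylationSummary:
    """Pooled weighted methylation level of one context.

    Pooling across replicates sums counts first (Σmc/Σcov), which is not the
    mean of per-replicate levels.
    """
    df = pool_sites(sites)
    sub = df[df["context"] == context]
    return MethylationSummary(
        context=context,
        mc_total=int(sub["mc"].sum()),
        cov_total=int(sub["cov"].sum()),
    )


def methylation_by_bin(
    sites,
    context: str,
    chrom_lengths: dict[str, int],
    bin_size: int = 100_000,
) -> pd.DataFrame:
    """Weighted methylation per fixed-width genomic bin.

    Bins are anchored at position 1 of each chromosome; the final partial bin
    is kept.  Bins with no covered cytosine of the context are excluded.
    Returns a frame with chrom, start (0-based), end, mc, cov, level.
    """
    df = pool_sites(sites)
    sub = df[df["context"] == context]
    out = []
    for chrom, length in chrom_lengths.items():
        n_bins = -(-length // bin_size)
        cdf = sub[sub["chrom"] == chrom]
        idx = (cdf["pos"].to_numpy() - 1) // bin_size
        mc = np.bincount(idx, weights=cdf["mc"].to_numpy(), minlength=n_bins)
        cov = np.bincount(idx, weights=cdf["cov"].to_numpy(), minlength=n_bins)
        for b in range(n_bins):
            if cov[b] > 0:
                out.append(
                    (
                        chrom,
                        b * bin_size,
                        min((b + 1) * bin_size, length),
                        int(mc[b]),
                        int(cov[b]),
                        mc[b] / cov[b],
                    )
                )
    return pd.DataFrame(out, columns=["chrom", "start", "end", "mc", "cov", "level"])


def methylation_by_100kb(sites, context: str, chrom_lengths: dict[str, int]) -> pd.DataFrame:
    """100-kb binned weighted methylation, the unit of the global box plots."""
    return methylation_by_bin(sites, context, chrom_lengths, bin_size=100_000)


# ---------------------------------------------------------------------------
# percent change and coverage arithmetic
# ---------------------------------------------------------------------------

def percent_change(level_before: float, level_after: float) -> float:
    """Signed percent change 100·(before − after)/before.

    Positive values are decreases, negative values increases, matching the
    convention of reporting a demethylation as "decreased by X%".
    """
    if level_before == 0:
        raise ValueError("percent change undefined for level_before = 0")
    return 100.0 * (level_before - level_after) / level_before


def describe_percent_change(level_before: float, level_after: float) -> tuple[float, str]:
    """(magnitude, direction) rendering of :func:`percent_change`."""
    pc = percent_change(level_before, level_after)
    if pc > 0:
        return pc, "decrease"
    if pc < 0:
        return -pc, "increase"
    return 0.0, "no change"


def estimate_coverage(
    unique_reads_rep1: int,
    unique_reads_rep2: int,
    read_length: int = 150,
    genome_size: float = 373e6,
) -> float:
    """Fold genome coverage of a paired-end two-replicate BS-seq library:
    (r1 + r2) × read_length × 2 / genome_size."""
    if unique_reads_rep1 < 0 or unique_reads_rep2 < 0:
        raise ValueError("read counts must be non-negative")
    return (unique_reads_rep1 + unique_reads_rep2) * read_length * 2 / genome_size


# ---------------------------------------------------------------------------
# metaplots
# ---------------------------------------------------------------------------

def metaplot(
    sites,
    features: pd.DataFrame,
    context: str,
    flank: int = 2000,
    n_body_bins: int = 20,
    n_flank_bins: int = 10,
) -> pd.DataFrame:
    """Average methylation profile over scaled features and fixed flanks.

    Each feature body is rescaled to ``n_body_bins`` bins and each flank to
    ``n_flank_bins``; counts are pooled (weighted) across features per bin.
    Minus-strand features are reversed so the profile reads 5'→3'.  Returns a
    frame with bin index, region label (upstream/body/downstream), mc, cov
    and level (NaN where no coverage).

    ``features`` needs columns chrom, start, end (0-based half-open), strand.
    """
    if len(features) == 0:
        raise ValueError("metaplot needs at least one feature")
    df = pool_sites(sites)
    sub = df[df["context"] == context]
    n_total = 2 * n_flank_bins + n_body_bins
    mc_bins = np.zeros(n_total)
    cov_bins = np.zeros(n_total)

    by_chrom = {
        chrom: (
            cdf["pos"].to_numpy() - 1,  # 0-based
            cdf["mc"].to_numpy(),
            cdf["cov"].to_numpy(),
        )
        for chrom, cdf in sub.sort_values("pos").groupby("chrom")
    }
    for feat in features.itertuples(index=False):
        if feat.chrom not in by_chrom:
            continue
        pos0, mc, cov = by_chrom[feat.chrom]
        start, end = int(feat.start), int(feat.end)
        lo = np.searchsorted(pos0, start - flank, side="left")
        hi = np.searchsorted(pos0, end + flank, side="left")
        if lo == hi:
            continue
        p = pos0[lo:hi]
        idx = np.empty(len(p), dtype=np.int64)
        up = p < start
        down = p >= end
        body = ~up & ~down
        if flank > 0:
            idx[up] = np.minimum(
                ((p[up] - (start - flank)) * n_flank_bins) // flank, n_flank_bins - 1
            )
            idx[down] = (
                n_flank_bins
                + n_body_bins
                + np.minimum(((p[down] - end) * n_flank_bins) // flank, n_flank_bins - 1)
            )
        width = end - start
        idx[body] = n_flank_bins + np.minimum(
            ((p[body] - start) * n_body_bins) // width, n_body_bins - 1
        )
        if feat.strand == "-":
            idx = n_total - 1 - idx
        np.add.at(mc_bins, idx, mc[lo:hi])
        np.add.at(cov_bins, idx, cov[lo:hi])

    region = (
        ["upstream"] * n_flank_bins + ["body"] * n_body_bins + ["downstream"] * n_flank_bins
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(cov_bins > 0, mc_bins / np.maximum(cov_bins, 1), np.nan)
    return pd.DataFrame(
        {
            "bin": np.arange(n_total),
            "region": region,
            "mc": mc_bins.astype(np.int64),
            "cov": cov_bins.astype(np.int64),
            "level": level,
        }
    )


# ---------------------------------------------------------------------------
# replicate QC
# ---------------------------------------------------------------------------

def replicate_correlation(
    track_rep1: MethylomeTrack,
    track_rep2: MethylomeTrack,
    context: str,
    chrom_lengths: dict[str, int],
    bin_size: int = 100_000,
) -> float:
    """Pearson correlation of binned weighted levels between two replicates.

    Only bins covered in both replicates enter; fewer than 3 shared bins
    raises :class:`InsufficientDataError`.
    """
    b1 = methylation_by_bin(track_rep1, context, chrom_lengths, bin_size)
    b2 = methylation_by_bin(track_rep2, context, chrom_lengths, bin_size)
    merged = b1.merge(b2, on=["chrom", "start"], suffixes=("_1", "_2"))
    if len(merged) < 3:
        raise InsufficientDataError(
            f"only {len(merged)} bins covered in both replicates; need >= 3"
        )
    r, _ = stats.pearsonr(merged["level_1"], merged["level_2"])
    return float(r)
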