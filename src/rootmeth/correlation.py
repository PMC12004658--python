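"""Promoter-bin CHH methylation versus gene expression.

For every gene the 2-kb region upstream of the TSS (strand-aware) is split
into ten 200-bp bins; per sample, each bin gets a pooled weighted CHH
level.  Expression (one value per sample, replicates averaged) is Pearson-
correlated with each bin across samples, the bin with the highest |r| is
the gene's "most related methylated promoter region", and
Benjamini–Hochberg FDR over all genes' best-bin p-values classifies genes
as positively / negatively correlated (q < 0.01) or unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .methylome import MethylomeTrack, pool_sites
from .synthetic import GenomeAnnotation

PROMOTER_SPAN = 2000
BIN_WIDTH = 200
Q_THRESHOLD = 0.01
MODIFIED_LEVEL = 0.5
MIN_SAMPLES = 4


# ---------------------------------------------------------------------------
# promoter bins
# ---------------------------------------------------------------------------

def promoter_bins(
    chrom: str,
    tss: int,
    strand: str,
    chrom_length: int,
    span: int = PROMOTER_SPAN,
    bin_width: int = BIN_WIDTH,
) -> pd.DataFrame:
    """Strand-aware upstream bins; bin 1 is nearest the TSS.

    Bins are truncated at chromosome edges; a TSS at the chromosome start of
    a plus-strand gene yields an empty frame (zero-length promoter).
    Columns: bin (1-based index), start, end (0-based half-open).
    """
    if not 0 <= tss <= chrom_length:
        raise ValueError(f"TSS {tss} outside chromosome of length {chrom_length}")
    n_bins = span // bin_width
    rows = []
    for i in range(1, n_bins + 1):
        if strand == "+":
            start, end = tss - i * bin_width, tss - (i - 1) * bin_width
        else:
            start, end = tss + (i - 1) * bin_width, tss + i * bin_width
        start, end = max(start, 0), min(end, chrom_length)
        if end > start:
            rows.append((i, start, end))
    return pd.DataFrame(rows, columns=["bin", "start", "end"]).assign(chrom=chrom)


# ---------------------------------------------------------------------------
# per-sample pooled site index for fast interval queries
# ---------------------------------------------------------------------------

class _SampleIndex:
    """Per-chromosome sorted positions with prefix sums of mc and cov."""

    def __init__(self, tracks, context: str):
        df = pool_sites(tracks)
        sub = df[df["context"] == context]
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, cdf in sub.groupby("chrom"):
            # two strands may share pos; aggregate then sort
            cdf = cdf.sort_values("pos")
            pos0 = cdf["pos"].to_numpy() - 1
            cmc = np.concatenate([[0], np.cumsum(cdf["mc"].to_numpy())])
            ccov = np.concatenate([[0], np.cumsum(cdf["cov"].to_numpy())])
            self.by_chrom[chrom] = (pos0, cmc, ccov)

    def counts(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return 0, 0
        pos0, cmc, ccov = entry
        lo = np.searchsorted(pos0, start, side="left")
        hi = np.searchsorted(pos0, end, side="left")
        return int(cmc[hi] - cmc[lo]), int(ccov[hi] - ccov[lo])


def bin_methylation(
    tracks_by_sample: dict[str, object],
    bins: pd.DataFrame,
    context: str = "CHH",
    indexes: dict[str, _SampleIndex] | None = None,
) -> pd.DataFrame:
    """Weighted methylation per promoter bin per sample (bins × samples).

    Replicates within a sample are pooled by summing counts; bins with zero
    coverage in a sample are NaN (missing).
    """
    if indexes is None:
        indexes = {s: _SampleIndex(t, context) for s, t in tracks_by_sample.items()}
    out = np.full((len(bins), len(indexes)), np.nan)
    for j, (sample, idx) in enumerate(indexes.items()):
        for i, b in enumerate(bins.itertuples(index=False)):
            mc, cov = idx.counts(b.chrom, b.start, b.end)
            if cov > 0:
                out[i, j] = mc / cov
    return pd.DataFrame(out, index=bins["bin"].to_numpy(), columns=list(indexes))


# ---------------------------------------------------------------------------
# best-bin correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    gene: str
    chrom: str
    bin: int | None
    bin_start: int | None
    bin_end: int | None
    r: float
    p_value: float
    n: int
    q_value: float = float("nan")
    sign_class: str = "none"

    @property
    def tested(self) -> bool:
        return np.isfinite(self.p_value)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Pearson r and two-sided p over pairwise-complete observations."""
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < MIN_SAMPLES:
        return np.nan, np.nan, n
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return np.nan, np.nan, n
    r = float(np.corrcoef(xs, ys)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return r, p, n


def best_bin_correlation(
    gene: str,
    expression: np.ndarray,
    bin_levels: pd.DataFrame,
    bins: pd.DataFrame,
    selection: str = "abs",
) -> CorrelationResult:
    """Select the promoter bin whose methylation correlates best with
    expression.

    ``selection="abs"`` maximises |r| (default; both correlation signs are
    biologically meaningful), ``"signed"`` maximises r.  Ties break toward
    the TSS-proximal bin.  Bins with undefined correlation (constant values
    or too few paired samples) are excluded; a gene with no usable bin has
    NaN statistics.
    """
    expr = np.asarray(expression, dtype=float)
    best: CorrelationResult | None = None
    best_key = -np.inf
    chrom = bins["chrom"].iat[0] if len(bins) else ""
    for (_, b), (_, levels) in zip(bins.iterrows(), bin_levels.iterrows()):
        r, p, n = _pearson(levels.to_numpy(dtype=float), expr)
        if not np.isfinite(r):
            continue
        key = abs(r) if selection == "abs" else r
        if key > best_key:  # strict: earlier (TSS-proximal) bin wins ties
            best_key = key
            best = CorrelationResult(
                gene=gene,
                chrom=chrom,
                bin=int(b["bin"]),
                bin_start=int(b["start"]),
                bin_end=int(b["end"]),
                r=r,
                p_value=p,
                n=n,
            )
    if best is None:
        return CorrelationResult(
            gene=gene, chrom=chrom, bin=None, bin_start=None, bin_end=None,
            r=np.nan, p_value=np.nan, n=0,
        )
    return best


# ---------------------------------------------------------------------------
# FDR and classification
# ---------------------------------------------------------------------------

def fdr_adjust_and_classify(
    results: list[CorrelationResult], q_threshold: float = Q_THRESHOLD
) -> list[CorrelationResult]:
    """Benjamini–Hochberg over all tested genes' best-bin p-values; genes
    with q < threshold are classed positive/negative by the sign of r."""
    tested = [res for res in results if res.tested]
    if tested:
        _, q_values, _, _ = multipletests(
            [res.p_value for res in tested], method="fdr_bh"
        )
        for res, q in zip(tested, q_values):
            res.q_value = float(q)
            if q < q_threshold:
                res.sign_class = "positive" if res.r > 0 else "negative"
            else:
                res.sign_class = "none"
    return results


@dataclass(frozen=True)
class CorrelationSummary:
    n_tested: int
    n_significant: int
    n_positive: int
    n_negative: int

    @property
    def fraction_percent(self) -> float:
        """Share of tested genes significantly correlated, in percent."""
        if self.n_tested == 0:
            return float("nan")
        return 100.0 * self.n_significant / self.n_tested


def summarize_classification(results: list[CorrelationResult]) -> CorrelationSummary:
    tested = [r for r in results if r.tested]
    pos = sum(1 for r in tested if r.sign_class == "positive")
    neg = sum(1 for r in tested if r.sign_class == "negative")
    return CorrelationSummary(
        n_tested=len(tested), n_significant=pos + neg, n_positive=pos, n_negative=neg
    )


def classified_fraction(n_significant: int, n_tested: int) -> float:
    """Percent of tested genes whose transcription tracks promoter
    methylation (the headline summary fraction)."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    return 100.0 * n_significant / n_tested


# ---------------------------------------------------------------------------
# whole-genome driver and the modified-promoter rule
# ---------------------------------------------------------------------------

def correlate_genes(
    tracks_by_sample: dict[str, object],
    annotation: GenomeAnnotation,
    expression: pd.DataFrame,
    context: str = "CHH",
    span: int = PROMOTER_SPAN,
    bin_width: int = BIN_WIDTH,
    q_threshold: float = Q_THRESHOLD,
    selection: str = "abs",
) -> pd.DataFrame:
    """Best-bin correlation with FDR classification for every gene.

    ``expression`` has one column per sample matching the keys of
    ``tracks_by_sample`` (replicates already averaged); genes missing from
    the matrix are skipped.
    """
    samples = list(tracks_by_sample)
    missing = [s for s in samples if s not in expression.columns]
    if missing:
        raise ValueError(f"expression matrix lacks sample columns {missing}")
    indexes = {s: _SampleIndex(tracks_by_sample[s], context) for s in samples}
    results: list[CorrelationResult] = []
    tss = annotation.tss()
    for gene_row in annotation.genes.itertuples(index=False):
        gene = gene_row.name
        if gene not in expression.index:
            continue
        bins = promoter_bins(
            gene_row.chrom,
            int(tss[gene]),
            gene_row.strand,
            annotation.chrom_lengths[gene_row.chrom],
            span,
            bin_width,
        )
        if len(bins) == 0:
            results.append(
                CorrelationResult(
                    gene=gene, chrom=gene_row.chrom, bin=None, bin_start=None,
                    bin_end=None, r=np.nan, p_value=np.nan, n=0,
                )
            )
            continue
        levels = bin_methylation({}, bins, context, indexes=indexes)
        expr = expression.loc[gene, samples].to_numpy(dtype=float)
        results.append(best_bin_correlation(gene, expr, levels, bins, selection))
    fdr_adjust_and_classify(results, q_threshold)
    columns = [
        "gene", "chrom", "bin", "bin_start", "bin_end",
        "r", "p_value", "n", "q_value", "sign_class",
    ]
    if not results:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "chrom": r.chrom,
                "bin": r.bin,
                "bin_start": r.bin_start,
                "bin_end": r.bin_end,
                "r": r.r,
                "p_value": r.p_value,
                "n": r.n,
                "q_value": r.q_value,
                "sign_class": r.sign_class,
            }
            for r in results
        ],
        columns=columns,
    )


def modified_promoter(
    tracks,
    chrom: str,
    tss: int,
    strand: str,
    chrom_length: int,
    context: str = "CHH",
    level_threshold: float = MODIFIED_LEVEL,
    span: int = PROMOTER_SPAN,
) -> bool | None:
    """Whether a promoter's pooled weighted CHH level exceeds the modified-
    promoter threshold (strict); None when the promoter has no coverage."""
    bins = promoter_bins(chrom, tss, strand, chrom_length, span=span, bin_width=span)
    if len(bins) == 0:
        return None
    idx = _SampleIndex(tracks, context)
    b = bins.iloc[0]
    mc, cov = idx.counts(chrom, int(b["start"]), int(b["end"]))
    if cov == 0:
        return None
    return mc / cov > level_threshold
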