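"""Synthetic genomes, BS-seq count tracks and expression matrices.

The generator emulates the structure of a laser-microdissection BS-seq /
RNA-seq developmental series over root-initiation stages: a small genome
with annotated genes and transposable elements (TEs), two-replicate
per-cytosine methylation counts in the CG/CHG/CHH contexts, and an RPKM
expression matrix.  Known-truth structure is planted so that every
downstream stage — DMR calling, TE-length enrichment and promoter
methylation–expression correlation — has a recoverable signal:

* short TEs (< 500 bp) are placed preferentially inside the 2-kb promoter
  regions upstream of transcription start sites;
* a configurable number of 50-bp windows inside those promoter TEs carry a
  planted CHH demethylation that declines monotonically across stages from
  ``baseline + planted_delta`` down to the baseline;
* a configurable fraction of genes is "linked": their expression follows the
  planted promoter methylation monotonically with a per-gene sign.

Cytosine positions and contexts derive from a simulated nucleotide sequence
(both strands), so context assignment is genome-driven rather than fixed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .methylome import (
    CONTEXTS,
    MethylomeTrack,
    read_cytosine_report,
    write_cytosine_report,
)

WINDOW_WIDTH = 50
PROMOTER_SPAN = 2000
SHORT_TE_CUTOFF = 500

# expression-model internals: log-scale effect of the planted methylation
# gradient on linked genes, and the per-observation log-normal noise
_LINK_SLOPE = 1.0
_LINK_NOISE_SD = 0.25
_UNLINKED_NOISE_SD = 0.4


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults describe the study-like fixture."""

    n_chromosomes: int = 1
    chrom_length: int = 1_000_000
    n_genes: int = 150
    n_tes: int = 300
    short_te_fraction: float = 0.6
    baseline_methylation: tuple[float, float, float] = (0.6, 0.3, 0.05)  # CG, CHG, CHH
    planted_dmr_count: int = 200
    planted_delta: float = 0.3
    depth_mean: float = 25.0
    n_samples: int = 2
    n_replicates: int = 2
    correlated_gene_fraction: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        for name, p in zip(CONTEXTS, self.baseline_methylation):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"baseline_methylation[{name}]={p} outside [0,1]")
        for name in ("short_te_fraction", "correlated_gene_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0,1]")
        if not 0.0 < self.planted_delta <= 1.0:
            raise ConfigError(f"planted_delta={self.planted_delta} outside (0,1]")
        if self.depth_mean <= 0:
            raise ConfigError(f"depth_mean={self.depth_mean} must be > 0")
        for name in ("n_chromosomes", "chrom_length", "n_replicates", "n_samples"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("n_genes", "n_tes", "planted_dmr_count"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.planted_dmr_count > 0 and self.n_samples < 2:
            raise ConfigError("planting DMRs needs at least 2 samples")

    @property
    def sample_names(self) -> list[str]:
        return [f"S{i}" for i in range(self.n_samples)]

    @property
    def replicate_names(self) -> list[str]:
        return [f"R{i + 1}" for i in range(self.n_replicates)]


@dataclass
class GenomeAnnotation:
    """Chromosome lengths plus strand-aware gene and TE intervals.

    Interval frames use 0-based half-open coordinates with columns
    chrom, start, end, name, strand.
    """

    chrom_lengths: dict[str, int]
    genes: pd.DataFrame
    tes: pd.DataFrame

    def tss(self) -> pd.Series:
        """TSS coordinate per gene: start for + strand, end for − strand."""
        g = self.genes
        return pd.Series(
            np.where(g["strand"] == "+", g["start"], g["end"]),
            index=g["name"].to_numpy(),
            name="tss",
        )

    def promoters(self, span: int = PROMOTER_SPAN) -> pd.DataFrame:
        """Strand-aware upstream promoter intervals, clipped to chromosomes."""
        g = self.genes
        tss = np.where(g["strand"] == "+", g["start"], g["end"])
        start = np.where(g["strand"] == "+", tss - span, tss)
        end = np.where(g["strand"] == "+", tss, tss + span)
        lengths = g["chrom"].map(self.chrom_lengths).to_numpy()
        return pd.DataFrame(
            {
                "chrom": g["chrom"].to_numpy(),
                "start": np.clip(start, 0, lengths),
                "end": np.clip(end, 0, lengths),
                "name": g["name"].to_numpy(),
                "strand": g["strand"].to_numpy(),
            }
        )


@dataclass
class GroundTruth:
    """What was planted: DMR windows and methylation-linked genes."""

    planted_windows: pd.DataFrame  # chrom, start, end, context, direction, gene
    linked_genes: list[tuple[str, int]] = field(default_factory=list)
    # true planted CHH proportion per sample (monotone gradient)
    planted_profile: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def planted_keys(self) -> set[tuple[str, int, int]]:
        return {
            (w.chrom, int(w.start), int(w.end))
            for w in self.planted_windows.itertuples(index=False)
        }


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _chrom_names(n: int) -> list[str]:
    return [f"chr{i + 1}" for i in range(n)]


def _split_counts(total: int, n_parts: int) -> list[int]:
    base, extra = divmod(total, n_parts)
    return [base + (1 if i < extra else 0) for i in range(n_parts)]


def generate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Place non-overlapping genes and promoter-biased TEs on toy chromosomes.

    Genes occupy disjoint slots with enough upstream room that each 2-kb
    promoter is gene-free; short TEs land inside promoters, long TEs are
    uniform over the chromosome.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    chroms = _chrom_names(config.n_chromosomes)
    chrom_lengths = {c: config.chrom_length for c in chroms}

    gene_rows = []
    genes_per_chrom = _split_counts(config.n_genes, config.n_chromosomes)
    gi = 0
    for chrom, n_genes in zip(chroms, genes_per_chrom):
        if n_genes == 0:
            continue
        slot = config.chrom_length // n_genes
        # a slot must fit promoter (2 kb) + shortest gene + margin
        if slot < PROMOTER_SPAN + 1000 + 100:
            raise ConfigError(
                f"infeasible packing: {n_genes} genes on {config.chrom_length} bp"
            )
        for k in range(n_genes):
            slot_start = k * slot
            length = int(rng.integers(800, min(2200, slot - PROMOTER_SPAN - 100)))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                lo = slot_start + PROMOTER_SPAN + 50
                hi = slot_start + slot - length
                start = int(rng.integers(lo, max(lo + 1, hi)))
                end = start + length
            else:
                hi = slot_start + slot - PROMOTER_SPAN - 50
                lo = slot_start + length
                end = int(rng.integers(lo, max(lo + 1, hi)))
                start = end - length
            gi += 1
            gene_rows.append((chrom, start, end, f"g{gi:05d}", strand))
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "name", "strand"])

    n_short = int(round(config.short_te_fraction * config.n_tes))
    te_rows = []
    ti = 0
    for j in range(config.n_tes):
        ti += 1
        name = f"te{ti:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if j < n_short:
            length = int(rng.integers(80, SHORT_TE_CUTOFF))
            if len(genes):
                g = genes.iloc[int(rng.integers(len(genes)))]
                if g["strand"] == "+":
                    p_start, p_end = g["start"] - PROMOTER_SPAN, g["start"]
                else:
                    p_start, p_end = g["end"], g["end"] + PROMOTER_SPAN
                start = int(rng.integers(p_start, p_end - length))
                te_rows.append((g["chrom"], start, start + length, name, strand))
                continue
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, config.chrom_length - length))
            te_rows.append((chrom, start, start + length, name, strand))
        else:
            length = int(rng.integers(1000, 6000))
            if length >= config.chrom_length:
                raise ConfigError("chromosome too short for a long TE")
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, config.chrom_length - length))
            te_rows.append((chrom, start, start + length, name, strand))
    tes = pd.DataFrame(te_rows, columns=["chrom", "start", "end", "name", "strand"])
    return GenomeAnnotation(chrom_lengths=chrom_lengths, genes=genes, tes=tes)


# ---------------------------------------------------------------------------
# methylome simulation
# ---------------------------------------------------------------------------

def _simulate_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    """Uniform random nucleotide sequence as int codes 0=A,1=C,2=G,3=T."""
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _cytosine_sites(seq: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(pos0, strand_code, context_code) for every cytosine on both strands.

    strand_code 0='+', 1='-'; context_code 0=CG, 1=CHG, 2=CHH.
    """
    n = len(seq)
    nxt1 = np.empty(n, dtype=np.int8)
    nxt1[:-1] = seq[1:]
    nxt1[-1] = 0
    nxt2 = np.empty(n, dtype=np.int8)
    nxt2[:-2] = seq[2:]
    nxt2[-2:] = 0
    prv1 = np.empty(n, dtype=np.int8)
    prv1[1:] = seq[:-1]
    prv1[0] = 0
    prv2 = np.empty(n, dtype=np.int8)
    prv2[2:] = seq[:-2]
    prv2[:2] = 0

    plus = np.flatnonzero(seq == 1)
    ctx_plus = np.where(nxt1[plus] == 2, 0, np.where(nxt2[plus] == 2, 1, 2))
    minus = np.flatnonzero(seq == 2)  # C on the minus strand
    ctx_minus = np.where(prv1[minus] == 1, 0, np.where(prv2[minus] == 1, 1, 2))

    pos0 = np.concatenate([plus, minus])
    strand = np.concatenate(
        [np.zeros(len(plus), dtype=np.int8), np.ones(len(minus), dtype=np.int8)]
    )
    context = np.concatenate([ctx_plus, ctx_minus]).astype(np.int8)
    order = np.lexsort((strand, pos0))
    return pos0[order], strand[order], context[order]


def _eligible_planted_windows(annotation: GenomeAnnotation) -> pd.DataFrame:
    """50-bp grid windows fully inside short TEs that lie in promoters."""
    rows = []
    seen: set[tuple[str, int]] = set()
    tes = annotation.tes
    short = tes[(tes["end"] - tes["start"]) < SHORT_TE_CUTOFF]
    for prom in annotation.promoters().itertuples(index=False):
        sub = short[
            (short["chrom"] == prom.chrom)
            & (short["start"] >= prom.start)
            & (short["end"] <= prom.end)
        ]
        for te in sub.itertuples(index=False):
            first = -(-te.start // WINDOW_WIDTH) * WINDOW_WIDTH
            for ws in range(first, te.end - WINDOW_WIDTH + 1, WINDOW_WIDTH):
                key = (te.chrom, ws)
                if key not in seen:
                    seen.add(key)
                    rows.append((te.chrom, ws, ws + WINDOW_WIDTH, prom.name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def simulate_methylome(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> tuple[list[MethylomeTrack], GroundTruth]:
    """Draw per-cytosine counts for every sample-replicate and plant DMRs.

    Coverage is negative-binomial with mean ``depth_mean`` and variance about
    twice the mean (uneven BS-seq depth); methylated counts are binomial
    around the context baseline.  Planted windows replace the CHH proportion
    with a monotone per-sample gradient from baseline+delta (first sample)
    down to baseline (last sample); replicates of a sample share the same
    expected proportion.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    chroms = list(annotation.chrom_lengths)

    eligible = _eligible_planted_windows(annotation)
    if config.planted_dmr_count > len(eligible):
        raise ConfigError(
            f"planted_dmr_count={config.planted_dmr_count} exceeds "
            f"{len(eligible)} eligible promoter-TE windows"
        )
    if config.planted_dmr_count > 0:
        pick = np.sort(
            rng.choice(len(eligible), size=config.planted_dmr_count, replace=False)
        )
        planted = eligible.iloc[pick].reset_index(drop=True)
    else:
        planted = eligible.iloc[:0].copy()
    planted["context"] = "CHH"
    planted["direction"] = "hypo"

    if config.n_samples > 1:
        grad = np.linspace(1.0, 0.0, config.n_samples)
    else:
        grad = np.zeros(1)
    base_chh = config.baseline_methylation[2]
    profile = np.clip(base_chh + config.planted_delta * grad, 0.0, 1.0)

    truth = GroundTruth(
        planted_windows=planted[["chrom", "start", "end", "context", "direction", "gene"]],
        planted_profile=profile,
    )

    baseline = np.asarray(config.baseline_methylation)
    per_chrom = []  # (chrom, pos0, strand_code, context_code, planted_mask)
    for chrom in chroms:
        seq = _simulate_sequence(rng, annotation.chrom_lengths[chrom])
        pos0, strand, context = _cytosine_sites(seq)
        mask = np.zeros(annotation.chrom_lengths[chrom], dtype=bool)
        for w in planted[planted["chrom"] == chrom].itertuples(index=False):
            mask[w.start : w.end] = True
        planted_site = mask[pos0] & (context == 2)
        per_chrom.append((chrom, pos0, strand, context, planted_site))

    strand_sym = np.array(["+", "-"])
    context_sym = np.array(CONTEXTS)
    tracks: list[MethylomeTrack] = []
    for s, sample in enumerate(config.sample_names):
        for replicate in config.replicate_names:
            frames = []
            for chrom, pos0, strand, context, planted_site in per_chrom:
                p = baseline[context]
                if planted_site.any():
                    p = p.copy()
                    p[planted_site] = profile[s]
                cov = rng.negative_binomial(config.depth_mean, 0.5, size=len(pos0))
                mc = rng.binomial(cov, p)
                covered = cov > 0
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": pos0[covered] + 1,
                            "strand": strand_sym[strand[covered]],
                            "context": context_sym[context[covered]],
                            "mc": mc[covered].astype(np.int64),
                            "cov": cov[covered].astype(np.int64),
                        }
                    )
                )
            sites = pd.concat(frames, ignore_index=True)
            tracks.append(MethylomeTrack(sample=sample, replicate=replicate, sites=sites))
    return tracks, truth


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(
    annotation: GenomeAnnotation, truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Log-normal RPKM matrix (genes × sample-replicates).

    Linked genes follow the planted promoter methylation gradient on the log
    scale with a per-gene sign (recorded in ``truth.linked_genes``); other
    genes vary independently of methylation.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 3])
    genes = annotation.genes["name"].tolist()
    columns = [
        f"{s}_{r}" for s in config.sample_names for r in config.replicate_names
    ]
    sample_of_col = np.repeat(np.arange(config.n_samples), config.n_replicates)

    candidates = sorted(set(truth.planted_windows["gene"])) if len(truth.planted_windows) else []
    n_linked = min(int(round(config.correlated_gene_fraction * len(genes))), len(candidates))
    linked = list(
        rng.choice(candidates, size=n_linked, replace=False)
    ) if n_linked else []
    signs = {g: int(rng.choice([-1, 1])) for g in linked}
    truth.linked_genes = sorted(signs.items())

    if config.n_samples > 1 and np.ptp(truth.planted_profile) > 0:
        z = (truth.planted_profile - truth.planted_profile.mean()) / truth.planted_profile.std()
    else:
        z = np.zeros(config.n_samples)

    base = rng.lognormal(mean=1.0, sigma=1.2, size=len(genes))
    values = np.empty((len(genes), len(columns)))
    for i, gene in enumerate(genes):
        if gene in signs:
            mu = np.log(base[i]) + signs[gene] * _LINK_SLOPE * z[sample_of_col]
            noise = rng.normal(0.0, _LINK_NOISE_SD, size=len(columns))
        else:
            mu = np.log(base[i]) * np.ones(len(columns))
            noise = rng.normal(0.0, _UNLINKED_NOISE_SD, size=len(columns))
        values[i] = np.exp(mu + noise)
    return pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=columns)


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

def write_bed6(df: pd.DataFrame, path) -> None:
    out = df[["chrom", "start", "end", "name"]].copy()
    out["score"] = 0
    out["strand"] = df["strand"].to_numpy()
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return df[["chrom", "start", "end", "name", "strand"]]


def write_fixture(
    directory,
    annotation: GenomeAnnotation,
    tracks: list[MethylomeTrack],
    matrix: pd.DataFrame,
    truth: GroundTruth,
) -> dict[str, str]:
    """Write the complete fixture as plain-text files; returns the file map."""
    os.makedirs(directory, exist_ok=True)
    paths: dict[str, str] = {}

    def p(name: str) -> str:
        paths[name] = os.path.join(directory, name)
        return paths[name]

    with open(p("chroms.tsv"), "w") as fh:
        for chrom, length in annotation.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")
    write_bed6(annotation.genes, p("genes.bed"))
    write_bed6(annotation.tes, p("tes.bed"))
    for track in tracks:
        write_cytosine_report(track, p(f"meth_{track.sample}_{track.replicate}.tsv"))
    matrix.to_csv(p("expression.tsv"), sep="\t")
    with open(p("truth.txt"), "w") as fh:
        for w in truth.planted_windows.itertuples(index=False):
            fh.write(
                f"planted_window\t{w.chrom}\t{w.start}\t{w.end}\t{w.context}\t{w.direction}\t{w.gene}\n"
            )
        for gene, sign in truth.linked_genes:
            fh.write(f"linked_gene\t{gene}\t{sign:+d}\n")
        levels = "\t".join(f"{x:.10g}" for x in truth.planted_profile)
        fh.write(f"planted_profile\t{levels}\n")
    return paths


def read_truth(path) -> GroundTruth:
    windows = []
    linked: list[tuple[str, int]] = []
    profile = np.zeros(0)
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "planted_window":
                windows.append(
                    (parts[1], int(parts[2]), int(parts[3]), parts[4], parts[5], parts[6])
                )
            elif parts[0] == "linked_gene":
                linked.append((parts[1], int(parts[2])))
            elif parts[0] == "planted_profile":
                profile = np.array([float(x) for x in parts[1:]])
    return GroundTruth(
        planted_windows=pd.DataFrame(
            windows, columns=["chrom", "start", "end", "context", "direction", "gene"]
        ),
        linked_genes=linked,
        planted_profile=profile,
    )


def read_fixture(directory):
    """Load a fixture directory back: (annotation, tracks, matrix, truth)."""
    chrom_lengths: dict[str, int] = {}
    with open(os.path.join(directory, "chroms.tsv")) as fh:
        for line in fh:
            chrom, length = line.split("\t")
            chrom_lengths[chrom] = int(length)
    annotation = GenomeAnnotation(
        chrom_lengths=chrom_lengths,
        genes=read_bed6(os.path.join(directory, "genes.bed")),
        tes=read_bed6(os.path.join(directory, "tes.bed")),
    )
    tracks = []
    for fname in sorted(os.listdir(directory)):
        if fname.startswith("meth_") and fname.endswith(".tsv"):
            stem = fname[len("meth_") : -len(".tsv")]
            sample, replicate = stem.rsplit("_", 1)
            tracks.append(read_cytosine_report(os.path.join(directory, fname), sample, replicate))
    matrix = pd.read_csv(os.path.join(directory, "expression.tsv"), sep="\t", index_col=0)
    truth = read_truth(os.path.join(directory, "truth.txt"))
    return annotation, tracks, matrix, truth


def simulate_all(config: SimulationConfig):
    """Run the three generator stages: (annotation, tracks, matrix, truth)."""
    annotation = generate_annotation(config)
    tracks, truth = simulate_methylome(annotation, config)
    matrix = simulate_expression(annotation, truth, config)
    return annotation, tracks, matrix, truth
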