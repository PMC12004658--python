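# rootmeth

Windowed differential-methylation calling, transposon-enrichment statistics
and promoter methylation–expression correlation for plant developmental
BS-seq / RNA-seq series — the kind of design where laser-microdissected
root-initiation stages (crown, lateral and embryonic root initials, stages
S0–S3) are profiled with two-replicate whole-genome bisulfite sequencing
and matched RPKM expression matrices.

## What it computes

**Global methylation summaries.** Weighted methylation levels per context
(CG/CHG/CHH), where the level of a region is Σmc/Σcov pooled over sites and
replicates; 100-kb bin distributions; gene/TE metaplots; replicate
correlations; the stage-to-stage percent change 100·(m_before −
m_after)/m_before with a two-proportion z-test on pooled counts.

**DMR calling.** The genome is tiled into 50-bp windows. A window is a DMR
between samples A and B when (i) each sample has ≥ 20 summed cytosine read
depth (two replicates together), (ii) the pooled level difference exceeds
0.5 / 0.3 / 0.1 for CG / CHG / CHH, (iii) the two-sided Fisher exact test
on the pooled 2×2 count table gives p < 0.05, and (iv) every A-replicate ×
B-replicate pairing shows a same-sign difference above the threshold.
DMRs are classed hypo/hyper and annotated by precedence TE > promoter >
gene body > intergenic.

**TE enrichment.** Lengths of TEs overlapped by DMR windows are compared
with TEs overlapped by 2000 random 50-bp windows per chromosome
(Mann–Whitney U), with the fraction of short TEs (< 500 bp) reported, plus
a strand-aware positional density profile of short TEs over genic regions.

**Expression analyses.** Transcribed-gene counts (RPKM > 1, replicates
averaged), strict DEG filtering (fold change > 4, q < 0.01), the
co-expression pre-filter (max RPKM > 2, CV > 1), and classical metric MDS
of Euclidean distances between expression profiles.

**Promoter correlation.** The 2-kb upstream promoter is split into ten
200-bp bins; per sample each bin gets a pooled weighted CHH level; the bin
with the highest |Pearson r| against expression across samples is the
gene's most related methylated promoter region; Benjamini–Hochberg FDR
(q < 0.01) over all genes' best-bin p-values classifies genes as
positively / negatively correlated. A promoter with pooled CHH level > 0.5
is "modified".

A synthetic-data generator (`rootmeth.synthetic`) produces toy genomes,
two-replicate cytosine-report tracks and expression matrices with planted,
known-truth hypo-CHH windows inside short promoter TEs and linked genes,
so every stage is testable end to end without external data.

## Worked example

```python
import rootmeth as rm

config = rm.SimulationConfig(seed=11)      # 1 Mb, 2 stages x 2 replicates,
annotation, tracks, matrix, truth = rm.simulate_all(config)

counts = rm.window_counts(tracks[2:4], tracks[:2],
                          annotation.chrom_lengths, "CHH")
dmrs = rm.call_dmrs(counts)
called = {(r.chrom, r.start, r.end) for r in dmrs.itertuples(index=False)}
planted = truth.planted_keys()
print(len(dmrs), len(planted & called) / len(planted))
# 200 1.0

level_s0 = rm.weighted_methylation(tracks[:2], "CHH").level
level_s1 = rm.weighted_methylation(tracks[2:4], "CHH").level
print(round(100 * level_s0, 2), round(100 * level_s1, 2))
# 5.31 5.0
print(rm.methylome.describe_percent_change(5.02, 3.31))
# (34.06374501992031, 'decrease')
```

The first block recovers all 200 planted hypo-CHH windows (sensitivity
1.0); the second shows the genome-wide weighted CHH levels of the two
simulated stages (the planted windows lift stage 0 slightly above the 5%
baseline) and the percent-change arithmetic on two observed global levels:
a 34.06% decrease.

The same pipeline runs from the shell:

```bash
rootmeth simulate --seed 11 --out fixture
rootmeth run-all --seed 11            # reads ./fixture, writes ./results
```

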