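# Methods

## Data model

All methylation data enter as cytosine reports: one row per sequenced
cytosine with chromosome, 1-based position, strand, context (CG, CHG, CHH;
H ∈ {A, C, T}), methylated-read count `mc` and total coverage `cov`.
Internally all interval arithmetic is 0-based half-open; written tables use
1-based inclusive coordinates. CG sites on the two strands are counted
independently — no CpG-pair destranding is applied anywhere.

Every summary uses the *weighted* methylation level: Σmc/Σcov over the
sites (and replicates) of a region. Pooling replicates therefore means
summing counts before dividing, which is deliberately not the mean of
per-replicate levels; a region with zero coverage carries an undefined
(NaN) level and is flagged rather than raising.

## DMR procedure

Chromosomes are tiled into disjoint 50-bp windows anchored at position 1
(the final window may be short). Per window, context and replicate, `mc`
and `cov` are summed over both strands. The four filters are conjunctive:

1. **Informative depth** — summed coverage ≥ 20 in each sample (the two
   replicates together). The depth sum, not the distinct-site count, is
   what is filtered; the alternative joint rule (A + B ≥ 20) is exposed as
   `informative_rule="joint"`. Requiring depth *per sample* is the default
   because the two-sample test needs information on both sides.
2. **Effect size** — |pooled level difference| strictly greater than
   0.5 (CG), 0.3 (CHG) or 0.1 (CHH).
3. **Significance** — two-sided Fisher exact p < 0.05 on the pooled table
   [[mc_A, cov_A − mc_A], [mc_B, cov_B − mc_B]].
4. **Replicate consistency** — every A-replicate × B-replicate cross
   pairing (four pairings at two replicates each) must individually exceed
   the context threshold with the same sign as the pooled difference.
   Within-sample pairings are excluded (they carry no differential sign);
   a pairing with zero coverage on either side fails the window —
   the conservative choice for an ambiguous case.

Direction is *hypo* when the first (later-stage) sample is lower. Windows
are reported individually and never merged. The Fisher test is computed
with exact integer arithmetic: hypergeometric numerators
C(cov_A, k)·C(cov_B, c1−k) are compared as integers and summed where they
do not exceed the observed table's numerator, with a single float division
at the end. This makes tie handling exact (no relative-epsilon rule is
needed) and the implementation agrees with a full-enumeration oracle to
machine precision on every table with total ≤ 60. Degenerate margins give
p = 1.

DMRs are annotated by any-overlap with precedence TE > promoter (2 kb
upstream of the TSS, strand-aware) > gene body > intergenic, so category
counts partition the DMR set.

## TE enrichment

Control windows are 50-bp intervals with uniformly random start positions,
2000 per chromosome, drawn with replacement (controls may overlap each
other). For a window set, the lengths of all overlapped TEs are collected
once per window–TE overlap event; a distinct-TE mode (each TE once) is
available. The two length distributions are compared with a two-sided
Mann–Whitney U test — the data are box-plot summaries of skewed length
distributions, so a rank test is the natural choice — together with
medians, quartiles and the fraction below the 500-bp short-TE cutoff.
The short-TE positional profile counts TE midpoints per scaled genic bin
(20 body bins, 10 per 2-kb flank by default), normalised by the bp each
bin represents, strand-aware.

## Expression analyses

Transcribed genes are those with mean-of-replicates RPKM strictly above 1;
a stricter all-replicates mode is provided. DEG filtering takes an
upstream differential-expression table as input (fold change as
later/earlier stage ratio) and keeps fold > 4 or < 1/4 with q < 0.01, all
strict. The co-expression pre-filter keeps genes with max RPKM > 2 and
coefficient of variation (sample standard deviation, ddof = 1, over the
mean) > 1; zero-mean genes are excluded as CV-undefined. MDS is classical
metric scaling: eigendecomposition of the double-centred squared Euclidean
distance matrix, coordinates from the top positive eigenpairs, residual
stress reported. For samples whose centred profiles span ≤ k dimensions
the k-dimensional embedding reproduces the distances exactly.

## Promoter correlation

The promoter is the 2-kb region strictly upstream of the TSS (start for
plus-strand genes, end for minus-strand), split into ten 200-bp bins with
bin 1 adjacent to the TSS, truncated at chromosome edges. Per sample, bins
get pooled weighted CHH levels; bins uncovered in a sample are missing and
drop out pairwise. Pearson r and its t-distribution p are computed per bin
over samples (at least 4 complete pairs required; constant vectors are
excluded), the bin with the maximum |r| is selected (ties to the
TSS-proximal bin; a signed-maximum mode exists), and Benjamini–Hochberg
adjustment over all genes' best-bin p-values classifies genes at q < 0.01
by the sign of r. Correlations use stage-level values — methylation pooled
across replicates, expression averaged — matching one observation per
stage. A promoter whose pooled CHH level strictly exceeds 0.5 is
"modified"; zero coverage is reported as not evaluable rather than false.

Because the best bin is chosen as a maximum over ten correlated candidates
*before* FDR adjustment, best-bin p-values are optimistically biased under
the null; the adjustment controls the FDR of the selected statistics, not
of a pre-registered single test. This selection effect is inherent to the
procedure and visible in the synthetic null as a small excess of
classified unlinked genes.

## Synthetic-data generator

The generator emulates the study design's structure, not its biology:

- **Genome** — uniform random nucleotide sequences (1 chromosome × 1 Mb by
  default); every C on either strand receives its context from the actual
  simulated sequence, so context proportions are genome-driven and the
  context-assignment code is genuinely exercised.
- **Annotation** — genes occupy disjoint slots with a guaranteed gene-free
  2-kb promoter; short TEs (80–499 bp, 60% of 300 TEs by default) are
  placed inside promoters, long TEs (1–6 kb) uniformly. This builds in the
  short-TE-at-promoters association that the TE-enrichment stage must
  recover.
- **Counts** — coverage is negative binomial with mean 25 and variance
  ≈ 2× the mean (uneven BS-seq depth); methylated counts are binomial at
  the context baselines (0.6 CG / 0.3 CHG / 0.05 CHH), typical plant-soma
  values with CHH at the few-percent level.
- **Planted DMRs** — 200 grid-aligned 50-bp windows fully inside short
  promoter TEs carry a CHH proportion that declines linearly across stages
  from baseline + 0.3 down to baseline. All planted windows are hypo
  (later stage lower), mirroring the predominance of demethylation during
  post-embryonic root initiation; with the default two stages the realised
  pooled difference equals the full 0.3 delta.
- **Expression** — log-normal RPKM (log-scale base spread 1.2). Linked
  genes (a configurable fraction with a planted promoter window) follow
  the planted methylation gradient on the log scale with slope ±1 per
  standardised unit and per-observation log-noise 0.25; unlinked genes get
  independent log-noise 0.4. The same monotone gradient thus powers both
  the two-sample DMR fixture and the nine-sample correlation fixture.

Fixing the seed fixes every output byte; the three generator stages draw
from independently keyed generators so results do not depend on call
order.

What the generator does **not** emulate: regional methylation
heterogeneity (outside planted windows, baselines are spatially constant,
so replicate bin-correlations on simulated data carry no biological
variance), TE-body hypermethylation gradients, linked CG/CHG dynamics,
bisulfite non-conversion, mapping bias, or overdispersed biological
replicate variance (replicates share exact expected proportions). Passing
tests therefore demonstrate correctness of the computations and
recoverability of planted signal at realistic depth and effect sizes — not
performance on real methylomes.

## Problem sizes and numerical choices

The test and acceptance fixtures use a 1-Mb genome at 25× depth (≈ 5 × 10⁵
cytosines per track), a 500-kb nine-stage fixture for correlation, and an
exhaustive Fisher sweep over all 2×2 tables with total ≤ 60 (635,376
tables) — sizes at which every planted quantity is recoverable with
comfortable statistical margins while the full suite runs in well under a
minute per stage. Thresholds never use ≥ where the rule says >; all strict
inequalities (difference, RPKM, fold change, CV, modified-promoter level)
are preserved exactly. Ties in best-bin selection go to the TSS-proximal
bin; ties in Fisher enumeration are exact by integer comparison.

## Known limitations

- The replicate-consistency filter assumes exactly the replicate structure
  given; samples with one replicate degenerate to the pooled comparison.
- Window-level Fisher tests on pooled counts ignore biological replicate
  overdispersion; the consistency filter is the procedure's only guard.
- Best-bin selection bias (above) inflates the nominal FDR of the
  correlation classification.
- The percent-change statistic is undefined for a zero "before" level and
  is reported as magnitude + direction, so a 34% decrease and a 34%
  increase differ only in the label.
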