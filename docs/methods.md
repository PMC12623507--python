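# Methods

## Scope and data model

The pipeline operates on per-sample, per-CpG methylation call tables
(methylated / total read counts), a sample sheet mapping samples to
tissue, lineage (CD4/CD8), CD69 status, donors and a pooled flag, gene
models, and a BED of partially methylated domains.  Internally all
coordinates are 0-based half-open; the Bismark coverage dialect
(1-based inclusive) is converted at the I/O boundary only.  Methylation
is a fraction in [0, 1] in memory and a 0–100 percentage only in
exports.  CpGs absent from a table are *missing* — RRBS capture gaps
are never coded as zero methylation.  CpG calls are assumed
strand-merged; gene strand is used only to orient TSS, UTRs and
promoter windows.

## Tiling and the DMR rule

Tiles are a fixed 500 bp grid anchored at 0, one grid per chromosome,
trailing partial tiles dropped.  Tile methylation is coverage-weighted,
Σmeth/Σtotal over CpGs with ≥ `min_cov_per_cpg` (default 3) reads; the
weighted form makes the statistic exactly the fraction of methylated
reads in the tile and is invariant to how CpGs partition the reads.
Population values are unweighted means over replicates — pooled
libraries already average donors at the DNA level, and weighting by
depth would let deep libraries dominate a population.  In strict mode
(default) a population value is missing when any replicate is missing,
so pairwise comparisons never mix replicate subsets.

A tile is a DMR for populations (A, B) iff both population values
exist, both populations cover at least 5 CpGs in the tile (the CpG
floor is a property of the *comparison*, preventing asymmetric-coverage
artifacts), and |m̄_A − m̄_B| ≥ 0.15.  The 15 % threshold is read as 15
percentage points of mean tile methylation; the alternative reading
(≥ 15 % of the tile's CpGs individually differential) is not
implemented.  Compiled sets are unions over tissue pairs within one
lineage × CD69 subset, with per-pair signed differences retained.  No
sliding windows, no merging of adjacent tiles, and no per-tile
hypothesis test (beta-binomial or Fisher testing is deliberately out of
scope): a DMR is a 500 bp unit.

The top-decile operation keeps DMRs at or above the 90th percentile of
the compiled |Δ|, ties included.  Genome fraction is total DMR bp over
total genome bp.

## PMD methylation

PMDs are an input (previously reported domains), never discovered de
novo.  Per domain and per sample the statistic is again Σmeth/Σtotal;
the global value aggregates read counts over all domains, which makes
it invariant to how domains are split into sub-intervals.  Overlapping
input domains are rejected rather than silently merged.

## Variance decomposition

*Donor variance*: per sample, the variance (denominator n; switchable
to n−1) and CV of its methylation values across the compiled DMRs.
Both variance and SD are reported, since either may be the quantity a
reader wants.  On compiled DMR sets these values are dominated by the
bimodality of the DMR methylation landscape, not by noise.

*PCA*: samples are observations, DMRs variables; per-DMR centering, no
variance scaling.  Missing entries are imputed with the per-DMR mean
across samples before fitting — mean imputation is
variance-conservative and keeps every sample.  Component signs follow a
deterministic convention (largest-|loading| element positive).
Held-out samples are projected with the *training* means and loadings,
so e.g. blood populations can be placed in a tissue-trained space
without refitting.

*MANOVA*: one-way MANOVA of the first k = 2 PC scores on tissue, using
Wilks' Λ with Rao's F approximation (exact for two response variables).
Two PCs are used because two components are what the ordination
displays; k is configurable.  The residual (within-tissue) variation is
donor-level variation, so F is the tissue-to-donor variance ratio.  A
singular within-group covariance raises an error; it is never silently
regularised.  With k = 1 the statistic reduces to the one-way ANOVA F,
computed directly.

*Clustering*: per-DMR Z-scores (population SD; constant rows map to
zero), Euclidean distance, Ward linkage for both DMR (row) and sample
(column) trees; flat labels by cutting at a requested cluster count.

## Annotation and gene ranking

Five feature classes: promoter (TSS ± 3 kb in strand coordinates), 5′
UTR, exon, intron, 3′ UTR.  Any overlap counts, a DMR may carry several
flags and genes — the classes are deliberately not a partition, so
composition fractions may sum above 1; `any_feature` is the fraction of
DMRs with at least one flag.  A DMR with no flag is intergenic.  The
regulatory filter keeps promoter or intronic DMRs.  Gene ranking counts
distinct promoter/intron DMRs per gene, breaking ties by the largest
|Δ| among those DMRs and then lexicographically; the ranking criterion
is a declared convention of this package.  Gene models carry one
transcript per gene; isoform collapsing is the data supplier's job.

## Locus statistics

Group comparisons use the two-sided Mann–Whitney U test: exact null
when the combined n ≤ 20 with no ties, otherwise the normal
approximation with tie correction.  Stars follow the conventional
scheme (**** < 10⁻⁴, *** < 10⁻³, ** < 0.01, * < 0.05).  No multiple-
testing correction by default — panels report raw stars — with
Benjamini–Hochberg available behind a flag.  Default pairing is every
tissue against a reference group (blood); all-pairs mode is available.
Methylation–expression association is ordinary least squares of
linear-scale expression on the DMR methylation fraction, p from the
two-sided t test on the slope; constant methylation is an error, not a
zero.

## Synthetic cohorts

The generator's defaults are the study design the pipeline targets:
six tissue groups (Bm, In, Sp, Lu, Sk, Bl), CD4 and CD8 lineages,
CD69+/− states with blood CD69− only, 3 replicates per population and 7
for blood, ~60 % of libraries pooled from 3 donors, ~40 % CpG capture,
mean 30× negative-binomial coverage (dispersion r = 5).  The default
genome is 500 kb across two chromosomes with 60 planted DMRs — sized so
a full cohort simulates in under a second while leaving hundreds of
null tiles; analyses scale linearly for larger genomes.

CpGs are placed in clusters (~12 CpGs, ~20 bp spacing, overall density
1 per 100 bp) and the baseline methylation state — a three-component
Beta mixture: CpG-island-like low (Beta(2,38)), intermediate
(Beta(8,8)), background high (Beta(38,2)) with weights 0.25/0.15/0.60 —
is assigned per cluster, so tiles are internally coherent, as real
methylomes are.  RRBS capture selects whole clusters until the target
CpG fraction is met, mirroring fragment-level capture; consequently the
captured landscape is shared across samples.

Planted DMRs occupy single 500 bp grid tiles with ≥ 5 captured CpGs
outside PMDs — ground truth is planted only where RRBS can see it,
otherwise recovery rates would conflate detection with capture.  Each
DMR is assigned one affected tissue; the direction adapts to the local
baseline (hypomethylation from high baselines, hypermethylation from
low), keeping effects inside the unit interval.  Donor effects are
Gaussian offsets per donor and region class (the three baseline states
and PMDs), attenuated by the local dynamic range 2·min(m, 1−m), so
inter-individual variability lives at intermediate methylation and
vanishes at saturation.  The default donor SD (0.05) was chosen as a
realistic inter-individual scale an order below the planted tissue
effect (0.4); the regime tests instead derive donor SD from the
targeted tissue-to-donor variance ratio (tissue variance per DMR is
δ²·1/6 for one affected tissue in six, so donor SD = δ/√12 puts tissue
variance at twice donor variance).  Inside PMDs the baseline is
replaced by the tissue's PMD level (defaults follow the qualitative
pattern of slight erosion in lung/skin and slight elevation in
intestine/spleen around a 0.54 baseline).  All effects combine
additively with clamping to [0.01, 0.99]; if more than 2 % of values
clamp by over 0.01 the configuration is reported as infeasible rather
than silently truncated.

Pooled libraries average the true methylation of their pool members
before read sampling.  Read totals are negative-binomial per captured
CpG (zero-read draws are simply absent); methylated counts are
binomial.  Every sample has its own seeded stream derived from the
cohort seed, so cohorts are byte-reproducible and a pooled sample of
identical donors is draw-for-draw identical to an individual one.

Expression is generated per gene as a + b·(1 − regional methylation) +
Gaussian noise (defaults a = 20, b = 50, σ = 5, CPM-like units), with
half the genes anchored to planted DMRs by promoter or first intron;
regressing expression on methylation recovers a slope of −b.

**What the synthetic cohorts do not emulate:** CpG-density biases of
real MspI digestion, bisulfite conversion error, strand-level effects,
copy-number variation, cell-type contamination, and correlated
megabase-scale methylation drift.  Passing recovery and calibration
tests therefore demonstrates the correctness of the computations and
the qualitative behaviour of the statistics under the assumed noise
model, not performance guarantees on real methylomes.

## Numerical and implementation choices

- Tile values are exact ratios of summed integer counts; the
  vectorised computation is verified against a per-CpG loop for exact
  equality.
- The 0.15 threshold is applied with ordinary `>=` on differences of
  count ratios; boundary behaviour is pinned by tests built from
  integer counts (149/1000 vs 150/1000).
- PCA uses a full SVD (deterministic); degenerate inputs (zero total
  variance) yield zero explained-variance ratios rather than NaN.
- Ward clustering on Z-scored rows; linkage heights are monotone and
  output is invariant to row order up to label permutation.
- The pipeline CLI writes full-precision TSVs for stage-to-stage
  hand-off and percent-scale (one decimal) matrices only as export
  copies, so re-running a stage from disk is lossless and two seeded
  runs are byte-identical.
- Figures are not produced; every plotted quantity in a typical atlas
  figure (PCA scores, Z-scored heatmap matrices, cluster labels, leaf
  orders, composition tables) is exported as text for external
  plotting.

## Known limitations

- Population means are unweighted over replicates; there is no
  shrinkage or depth weighting across replicates.
- No statistical test accompanies the DMR threshold rule; false
  positives are controlled only by the effect-size and coverage
  thresholds.
- Mean imputation before PCA/clustering shrinks the variance of
  heavily missing DMRs toward zero.
- The MANOVA treats samples as exchangeable within tissue; donor
  pairing across tissues (the same organ donor contributing several
  tissues) is not modelled as a random effect.
- Annotation assumes one transcript per gene and takes any overlap as
  membership; there is no promoter/gene-body priority hierarchy.
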