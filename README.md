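# tmethatlas

Tiled differentially-methylated-region (DMR) analysis for methylome
atlases of human tissue memory T cells (Tm), built for RRBS-style
per-CpG call tables.  The package is aimed at epigenomics analysts who
have per-sample Bismark-coverage files for populations structured by
tissue (bone marrow, intestine, spleen, lung, skin, blood), lineage
(CD4/CD8) and residency marker (CD69+/−), and who want reproducible
tissue-specific methylation signatures rather than one-off notebook
analyses.  Because the original atlas data of this kind are
controlled-access, the package ships a first-class synthetic cohort
generator with planted ground truth, so every stage is testable end to
end.

## What it computes

**Tile methylation.** The genome is cut into fixed, non-overlapping
500 bp tiles anchored at coordinate 0.  For sample *s* and tile *t*,
methylation is the coverage-weighted fraction over the tile's CpGs with
at least 3 reads:

    m(s, t) = Σ_i meth_i / Σ_i total_i

**DMR rule.** Population means are unweighted averages of replicate
tile values.  A tile is a DMR for a pair of tissue populations (A, B)
when both means exist, both populations cover ≥ 5 CpGs in the tile, and
|m̄_A − m̄_B| ≥ 0.15 (15 percentage points).  The *compiled* DMR set of
a lineage × CD69 subset is the union over all tissue pairs, carrying
per-pair signed differences and the maximal absolute difference.

**Downstream statistics.**

- weighted methylation over partially methylated domains (PMDs),
  supplied as a BED of previously reported domains;
- per-sample variance / CV of methylation across compiled DMRs
  (donor stability);
- PCA of samples over DMRs with held-out projection (e.g. blood
  populations projected onto a tissue-trained space), and one-way
  MANOVA of the first k PC scores on tissue (Wilks' Λ, Rao's F) — the
  tissue-to-donor variance ratio;
- per-DMR Z-scoring and Euclidean/Ward hierarchical clustering of DMRs
  and samples;
- annotation of DMRs against five genomic features (promoter = TSS
  ± 3 kb, 5′ UTR, exon, intron, 3′ UTR), feature composition, the
  regulatory (promoter-or-intron) filter, and gene ranking for external
  enrichment tools;
- Mann–Whitney/Wilcoxon rank tests between tissue groups with the
  conventional star scheme, and ordinary least-squares regression of
  linear-scale gene expression on DMR methylation.

The synthetic generator emulates the atlas design: clustered CpGs,
~40 % RRBS capture, negative-binomial read depth, a bimodal Beta-mixture
baseline, 500 bp planted tissue-specific DMRs, donor random effects,
3-donor pooled libraries and tissue-shifted PMD blocks.

## Worked example

```python
from tmethatlas import (SimConfig, simulate_cohort, build_tile_grid,
                        build_tile_matrix, population_means,
                        compile_subset_dmrs, genome_fraction, annotate_dmrs,
                        feature_composition, pca_fit, manova_tissue)

cfg = SimConfig(seed=1)                         # default atlas design, 500 kb genome
tables, sheet, genes, truth = simulate_cohort(cfg)

tiles = build_tile_grid(cfg.chrom_lengths, tile_size=500)
tm = build_tile_matrix(list(tables.values()), tiles, min_cov_per_cpg=3)

sub = sheet.subset(lineage="CD4", cd69="pos")
pops = population_means(tm.select_samples(sub.sample_ids), sub, group_by=("tissue",))
dmrs = compile_subset_dmrs(pops, subset=("CD4", "pos"))
print(len(dmrs), genome_fraction(dmrs, cfg.chrom_lengths))

comp = feature_composition(annotate_dmrs(dmrs, genes, tss_flank=3000))
vals = tm.values.loc[dmrs.tile_ids, sub.sample_ids].dropna(how="any")
res = pca_fit(vals, n_components=2)
mv = manova_tissue(res.scores, sub.tissue_of()[res.scores.index], k=2)
print(comp["any_feature"], mv.F, mv.p)
```

Output for seed 1:

```
74 samples, 60 planted DMRs
compiled DMRs: 50 (5.0% of the genome)
any-feature fraction: 0.76  promoter: 0.72
MANOVA (tissue): F = 1128.7, p = 1.07e-22
```

Read: the CD4 CD69+ subset of the simulated cohort yields 50 compiled
DMR tiles covering 5 % of the 500 kb genome; 76 % of them touch at
least one annotated genomic feature; and tissue identity separates the
samples overwhelmingly relative to donor variation (the MANOVA F is
the tissue-to-donor variance ratio on the first two PCs).

The same pipeline runs from the shell, stage by stage or end to end:

```sh
tmethatlas all --outdir out --seed 1
```

which writes call tables, tile matrices, compiled DMR BED/TSV sets,
PMD methylation, PCA/MANOVA reports, cluster labels, annotations, gene
lists, Wilcoxon and regression tables, plus a manifest of every
artifact.

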