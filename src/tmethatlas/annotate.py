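"""Genomic-feature annotation of DMRs and gene ranking.

Each DMR is tested for overlap against five feature classes of the gene
model — promoter (TSS +/- 3 kb, strand-oriented), 5' UTR, exon, intron,
3' UTR — any overlap counts and a DMR may carry several flags and
several genes (the classes are not a partition).  A DMR with no flag is
intergenic.  The regulatory filter keeps promoter or intronic DMRs,
the subset with a plausible cis-regulatory role; gene ranking counts
promoter/intron DMRs per gene for export to external enrichment tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .dmr import DMRSet
from .io import Gene, GeneModel

FEATURES = ("promoter", "utr5", "exon", "intron", "utr3")


@dataclass
class AnnotatedDMRSet:
    """DMRSet plus per-DMR feature flags and associated genes.

    ``annotations`` (indexed like ``dmr_set.dmrs``) columns:
    ``flags`` — frozenset drawn from promoter/utr5/exon/intron/utr3,
    or {'intergenic'} when empty; ``genes`` — list of
    (gene_id, relation, distance_to_tss) with distance measured from
    the DMR midpoint, strand-oriented (negative = upstream of the TSS).
    """

    dmr_set: DMRSet
    annotations: pd.DataFrame
    tss_flank: int

    def __len__(self) -> int:
        return len(self.annotations)


def _feature_intervals(gene: Gene, tss_flank: int):
    yield "promoter", gene.promoter(tss_flank)
    for iv in gene.utr5:
        yield "utr5", iv
    for iv in gene.exons:
        yield "exon", iv
    for iv in gene.introns():
        yield "intron", iv
    for iv in gene.utr3:
        yield "utr3", iv


def annotate_dmrs(dmr_set: DMRSet, genes: GeneModel,
                  tss_flank: int = 3000) -> AnnotatedDMRSet:
    """Overlap every DMR with every gene's feature intervals."""
    trees: dict[str, IntervalTree] = {}
    for gi, gene in enumerate(genes):
        tree = trees.setdefault(gene.chrom, IntervalTree())
        for feature, (s, e) in _feature_intervals(gene, tss_flank):
            if s < e:
                tree.addi(s, e, (gi, feature))
    flags_col, genes_col = [], []
    for tid, row in dmr_set.dmrs.iterrows():
        chrom, start, end = row["chrom"], int(row["start"]), int(row["end"])
        mid = (start + end) // 2
        hits = trees[chrom].overlap(start, end) if chrom in trees else ()
        flags: set[str] = set()
        per_gene: dict[int, set[str]] = {}
        for h in hits:
            gi, feature = h.data
            flags.add(feature)
            per_gene.setdefault(gi, set()).add(feature)
        assoc = []
        for gi in sorted(per_gene):
            gene = genes.genes[gi]
            dist = mid - gene.tss if gene.strand == "+" else gene.tss - mid
            for feature in sorted(per_gene[gi]):
                assoc.append((gene.gene_id, feature, int(dist)))
        flags_col.append(frozenset(flags) if flags else frozenset({"intergenic"}))
        genes_col.append(assoc)
    ann = pd.DataFrame({"flags": flags_col, "genes": genes_col},
                       index=dmr_set.dmrs.index)
    return AnnotatedDMRSet(dmr_set, ann, tss_flank)


def feature_composition(ann: AnnotatedDMRSet) -> pd.Series:
    """Per-feature DMR fraction plus the any-feature fraction.

    Fractions are per feature (a DMR counts once in every class it
    overlaps) so they may sum above 1.  ``any_feature`` is the fraction
    of DMRs with at least one non-intergenic flag.
    """
    n = len(ann)
    if n == 0:
        raise ValueError("feature_composition on an empty set")
    counts = {f: 0 for f in FEATURES}
    counts["intergenic"] = 0
    any_feature = 0
    for flags in ann.annotations["flags"]:
        for f in flags:
            counts[f] += 1
        if "intergenic" not in flags:
            any_feature += 1
    out = {f: counts[f] / n for f in FEATURES}
    out["intergenic"] = counts["intergenic"] / n
    out["any_feature"] = any_feature / n
    return pd.Series(out)


def filter_regulatory(ann: AnnotatedDMRSet) -> DMRSet:
    """DMRs within the TSS flank (promoter flag) or inside an intron."""
    keep = ann.annotations["flags"].map(lambda fl: bool(fl & {"promoter", "intron"}))
    return DMRSet(ann.dmr_set.subset, ann.dmr_set.dmrs[keep.values])


def rank_genes(ann: AnnotatedDMRSet, n: int = 3000) -> list[str]:
    """Top genes by number of associated promoter/intron DMRs.

    Score = count of distinct promoter/intron DMRs touching the gene;
    ties broken by the largest max_abs_diff among those DMRs, then by
    gene_id.  The output is a plain gene list for external enrichment.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    counts: dict[str, set[str]] = {}
    best_diff: dict[str, float] = {}
    diffs = ann.dmr_set.dmrs["max_abs_diff"]
    for tid, assoc in ann.annotations["genes"].items():
        for gene_id, relation, _dist in assoc:
            if relation in ("promoter", "intron"):
                counts.setdefault(gene_id, set()).add(tid)
                d = float(diffs.loc[tid])
                if d > best_diff.get(gene_id, -1.0):
                    best_diff[gene_id] = d
    ranked = sorted(counts,
                    key=lambda g: (-len(counts[g]), -best_diff[g], g))
    return ranked[:n]


def write_annotations(ann: AnnotatedDMRSet, path: str | Path) -> None:
    """TSV: dmr_id, flags, gene(relation@distance) triples."""
    rows = []
    for tid, row in ann.annotations.iterrows():
        flags = ";".join(sorted(row["flags"]))
        genes = ";".join(f"{g}|{rel}|{d}" for g, rel, d in row["genes"])
        rows.append((tid, flags, genes))
    pd.DataFrame(rows, columns=["dmr_id", "flags", "genes"]).to_csv(
        path, sep="\t", index=False)


def write_gene_list(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(g + "\n" for g in genes))
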