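"""Reading and writing the text formats the pipeline touches.

Coordinate convention: everything in memory is 0-based, half-open (BED
native).  The single place where 1-based inclusive coordinates appear is
the Bismark coverage dialect, converted on the way in and out.  CpG
methylation is carried as integer read counts; fractions are derived and
percentages appear only at export.  Missing CpGs (RRBS capture gaps) are
represented by absence from the table, never by a zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TISSUES = ("Bm", "In", "Sp", "Lu", "Sk", "Bl")
LINEAGES = ("CD4", "CD8")
CD69_STATES = ("pos", "neg")


class FormatError(ValueError):
    """A file does not parse under the declared dialect."""


# ---------------------------------------------------------------------------
# CpG call tables
# ---------------------------------------------------------------------------

@dataclass
class CpGCallTable:
    """Per-sample CpG methylation calls.

    ``calls`` has columns ``chrom`` (str), ``pos`` (0-based int),
    ``meth`` and ``total`` (read counts).  One row per CpG site, sorted
    by (chrom, pos); sites are strand-merged.
    """

    sample_id: str
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.calls
        required = ["chrom", "pos", "meth", "total"]
        if list(df.columns[:4]) != required:
            df = df[required]
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        if len(df):
            if (df["total"] <= 0).any():
                raise ValueError(f"{self.sample_id}: non-positive total read count")
            if (df["meth"] < 0).any() or (df["meth"] > df["total"]).any():
                raise ValueError(f"{self.sample_id}: meth count outside [0, total]")
            dup = df.duplicated(["chrom", "pos"])
            if dup.any():
                raise ValueError(f"{self.sample_id}: duplicate CpG positions")
        self.calls = df

    @property
    def n_sites(self) -> int:
        return len(self.calls)

    def fractions(self) -> pd.Series:
        """Per-CpG methylation fraction meth/total, in [0, 1]."""
        return self.calls["meth"] / self.calls["total"]


def read_cpg_calls(path: str | Path, format: str = "bismark_cov",
                   sample_id: str | None = None) -> CpGCallTable:
    """Read a per-CpG call file.

    ``bismark_cov``: chrom, start(1-based), end(1-based inclusive),
    percent methylation, count methylated, count unmethylated.  The
    percent column is ignored in favour of the counts.

    ``bedgraph_counts``: chrom, start(0-based), end, count methylated,
    count total.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.name.split(".")[0]
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            try:
                if format == "bismark_cov":
                    chrom, start, _end, _pct, cm, cu = parts[:6]
                    pos = int(start) - 1
                    meth, total = int(cm), int(cm) + int(cu)
                elif format == "bedgraph_counts":
                    chrom, start, _end, cm, ct = parts[:5]
                    pos, meth, total = int(start), int(cm), int(ct)
                else:
                    raise FormatError(f"unknown CpG call format {format!r}")
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed line: {line!r}") from exc
            if meth > total:
                raise FormatError(f"{path}:{lineno}: meth count {meth} exceeds total {total}")
            rows.append((chrom, pos, meth, total))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "total"])
    return CpGCallTable(sample_id=sample_id, calls=df)


def write_cpg_calls(table: CpGCallTable, path: str | Path,
                    format: str = "bismark_cov") -> None:
    """Write calls; inverse of :func:`read_cpg_calls` for both dialects."""
    df = table.calls
    with open(path, "w") as fh:
        if format == "bismark_cov":
            for chrom, pos, meth, total in df.itertuples(index=False):
                pct = 100.0 * meth / total
                fh.write(f"{chrom}\t{pos + 1}\t{pos + 1}\t{pct:.6g}\t{meth}\t{total - meth}\n")
        elif format == "bedgraph_counts":
            for chrom, pos, meth, total in df.itertuples(index=False):
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{meth}\t{total}\n")
        else:
            raise FormatError(f"unknown CpG call format {format!r}")


def write_bedgraph(table: CpGCallTable, path: str | Path) -> None:
    """Genome-browser track: 4-column bedGraph, value = percent 0-100."""
    with open(path, "w") as fh:
        for chrom, pos, meth, total in table.calls.itertuples(index=False):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{100.0 * meth / total:.6g}\n")


# ---------------------------------------------------------------------------
# Interval sets (DMR / PMD tracks)
# ---------------------------------------------------------------------------

@dataclass
class IntervalSet:
    """Named set of genomic intervals, 0-based half-open.

    ``intervals`` columns: chrom, start, end, plus optional ``label``
    (default '.') and ``score`` (int in [0, 1000], default 0).
    """

    name: str
    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.intervals.copy()
        if "label" not in df.columns:
            df["label"] = "."
        if "score" not in df.columns:
            df["score"] = 0
        df = df[["chrom", "start", "end", "label", "score"]]
        if len(df):
            if (df["start"] < 0).any():
                raise ValueError(f"{self.name}: negative coordinates")
            if (df["start"] >= df["end"]).any():
                raise ValueError(f"{self.name}: empty or inverted interval")
            if (df["score"] < 0).any() or (df["score"] > 1000).any():
                raise ValueError(f"{self.name}: score outside [0, 1000]")
        self.intervals = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)

    def sorted(self) -> "IntervalSet":
        df = self.intervals.sort_values(["chrom", "start", "end"], kind="mergesort")
        return IntervalSet(self.name, df.reset_index(drop=True))

    def total_bp(self) -> int:
        df = self.intervals
        return int((df["end"] - df["start"]).sum())

    def has_overlaps(self) -> bool:
        """True if any two intervals on one chromosome overlap."""
        for _, sub in self.intervals.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            if (sub["start"].values[1:] < sub["end"].values[:-1]).any():
                return True
        return False


def read_intervals(path: str | Path, name: str | None = None) -> IntervalSet:
    """Read BED3/BED6 into an IntervalSet."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                label = parts[3] if len(parts) > 3 else "."
                score = int(float(parts[4])) if len(parts) > 4 and parts[4] != "." else 0
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed BED line") from exc
            rows.append((chrom, start, end, label, score))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "score"])
    return IntervalSet(name or path.stem, df)


def write_intervals(iset: IntervalSet, path: str | Path) -> None:
    """Write BED6: chrom, start, end, label, score, strand '.'."""
    with open(path, "w") as fh:
        for chrom, start, end, label, score in iset.intervals.itertuples(index=False):
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\t{score}\t.\n")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]          # sorted, non-overlapping
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: missing or invalid strand {self.strand!r}")
        exons = sorted(self.exons)
        for (s1, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        if any(s >= e for s, e in exons):
            raise ValueError(f"{self.gene_id}: empty exon")
        self.exons = exons

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """0-based TSS: transcript start on '+', transcript end - 1 on '-'."""
        return self.start if self.strand == "+" else self.end - 1

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons."""
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1]

    def promoter(self, tss_flank: int = 3000) -> tuple[int, int]:
        """Window of ``tss_flank`` bp both sides of the TSS, strand-oriented.

        In strand coordinates the window is [-flank, +flank) around the
        TSS; on the minus strand that maps to genomic
        [tss - flank + 1, tss + flank + 1).
        """
        if self.strand == "+":
            lo, hi = self.tss - tss_flank, self.tss + tss_flank
        else:
            lo, hi = self.tss - tss_flank + 1, self.tss + tss_flank + 1
        return max(lo, 0), hi


@dataclass
class GeneModel:
    """One transcript per gene; multi-isoform collapse is upstream's job."""

    genes: list[Gene]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene_id in GeneModel")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def by_id(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def _bed12_blocks(start: int, sizes: str, starts: str) -> list[tuple[int, int]]:
    bsizes = [int(x) for x in sizes.rstrip(",").split(",")]
    bstarts = [int(x) for x in starts.rstrip(",").split(",")]
    return [(start + bs, start + bs + sz) for bs, sz in zip(bstarts, bsizes)]


def _clip(intervals: list[tuple[int, int]], lo: int, hi: int) -> list[tuple[int, int]]:
    out = []
    for s, e in intervals:
        s2, e2 = max(s, lo), min(e, hi)
        if s2 < e2:
            out.append((s2, e2))
    return out


def read_gene_models(path: str | Path, format: str = "bed12") -> GeneModel:
    """Read gene models from BED12 or a minimal GTF.

    BED12: exons from the block fields; 5'/3' UTRs derived from
    thickStart/thickEnd (CDS span), oriented by strand.

    Minimal GTF: feature types ``exon``, ``five_prime_utr`` and
    ``three_prime_utr`` grouped by a ``gene_id "..."`` attribute.
    """
    path = Path(path)
    genes: list[Gene] = []
    if format == "bed12":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                p = line.split("\t")
                if len(p) < 12:
                    raise FormatError(f"{path}:{lineno}: BED12 needs 12 fields")
                chrom, start, end = p[0], int(p[1]), int(p[2])
                name, strand = p[3], p[5]
                thick_s, thick_e = int(p[6]), int(p[7])
                exons = _bed12_blocks(start, p[10], p[11])
                if exons[0][0] != start or exons[-1][1] != end:
                    raise FormatError(f"{path}:{lineno}: blocks do not span chromStart..chromEnd")
                if thick_s < thick_e:
                    left = _clip(exons, start, thick_s)
                    right = _clip(exons, thick_e, end)
                else:                       # non-coding: no UTRs
                    left, right = [], []
                utr5, utr3 = (left, right) if strand == "+" else (right, left)
                genes.append(Gene(name, chrom, strand, exons, utr5, utr3))
    elif format == "gtf_min":
        acc: dict[str, dict] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                p = line.split("\t")
                if len(p) < 9:
                    raise FormatError(f"{path}:{lineno}: GTF needs 9 fields")
                chrom, _src, ftype, start, end, _score, strand, _frame, attrs = p[:9]
                if ftype not in ("exon", "five_prime_utr", "three_prime_utr"):
                    continue
                gid = None
                for item in attrs.split(";"):
                    item = item.strip()
                    if item.startswith("gene_id"):
                        gid = item.split(None, 1)[1].strip().strip('"')
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
                if strand not in ("+", "-"):
                    raise FormatError(f"{path}:{lineno}: missing strand")
                rec = acc.setdefault(gid, {"chrom": chrom, "strand": strand,
                                           "exon": [], "five_prime_utr": [], "three_prime_utr": []})
                rec[ftype].append((int(start) - 1, int(end)))  # GTF is 1-based inclusive
        for gid, rec in acc.items():
            genes.append(Gene(gid, rec["chrom"], rec["strand"], rec["exon"],
                              sorted(rec["five_prime_utr"]), sorted(rec["three_prime_utr"])))
    else:
        raise FormatError(f"unknown gene model format {format!r}")
    return GeneModel(genes)


def write_gene_models(model: GeneModel, path: str | Path) -> None:
    """Write BED12; UTR spans become the non-thick exon portions."""
    with open(path, "w") as fh:
        for g in model.genes:
            utr = sorted(g.utr5 + g.utr3)
            thick_s, thick_e = g.start, g.end
            # CDS = transcript span minus leading/trailing UTR blocks
            for s, e in utr:
                if s == thick_s:
                    thick_s = e
            for s, e in reversed(utr):
                if e == thick_e:
                    thick_e = s
            if thick_s >= thick_e:
                thick_s = thick_e = g.start
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            starts = ",".join(str(s - g.start) for s, _ in g.exons) + ","
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                     f"{thick_s}\t{thick_e}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n")


# ---------------------------------------------------------------------------
# Sample sheets
# ---------------------------------------------------------------------------

@dataclass
class SampleSheet:
    """Sample metadata driving all grouping.

    ``samples`` columns: sample_id, tissue, lineage, cd69, donors
    (list of donor ids), pooled (bool).  A sample is pooled iff it has
    more than one donor.
    """

    samples: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.samples
        df = df[["sample_id", "tissue", "lineage", "cd69", "donors", "pooled"]].reset_index(drop=True)
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample sheet")
        for sid, donors, pooled in df[["sample_id", "donors", "pooled"]].itertuples(index=False):
            if bool(pooled) != (len(donors) > 1):
                raise ValueError(f"{sid}: pooled flag inconsistent with donor count")
        self.samples = df

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    def subset(self, lineage: str | None = None, cd69: str | None = None,
               tissue: str | None = None) -> "SampleSheet":
        df = self.samples
        if lineage is not None:
            df = df[df["lineage"] == lineage]
        if cd69 is not None:
            df = df[df["cd69"] == cd69]
        if tissue is not None:
            df = df[df["tissue"] == tissue]
        return SampleSheet(df.reset_index(drop=True))

    def subsets(self) -> list[tuple[str, str]]:
        """(lineage, cd69) combinations present, in sorted order."""
        pairs = self.samples[["lineage", "cd69"]].drop_duplicates()
        return sorted(map(tuple, pairs.itertuples(index=False)))

    def tissue_of(self) -> pd.Series:
        return self.samples.set_index("sample_id")["tissue"]


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "tissue", "lineage", "cd69", "donors", "pooled"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
    df["donors"] = df["donors"].map(lambda s: [d for d in str(s).split(";") if d])
    df["pooled"] = df["pooled"].map(lambda s: str(s).lower() in ("true", "1", "yes"))
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    df = sheet.samples.copy()
    df["donors"] = df["donors"].map(";".join)
    df["pooled"] = df["pooled"].map(lambda b: "true" if b else "false")
    df.to_csv(path, sep="\t", index=False)
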