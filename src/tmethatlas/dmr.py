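"""Fixed-grid tiling and differentially methylated region (DMR) calling.

The genome is cut into non-overlapping tiles (default 500 bp) anchored
at coordinate 0.  Per sample, tile methylation is the coverage-weighted
fraction sum(meth) / sum(total) over CpGs passing a per-CpG coverage
floor.  A tile is a DMR for a pair of population groups when both group
means exist, both groups have at least ``min_cpgs`` covered CpGs in the
tile, and the absolute difference of the group means is at least
``delta`` (default 0.15, i.e. 15 percentage points).  The compiled DMR
set of a lineage x CD69 subset is the union over all tissue pairs.

No sliding windows, no merging of adjacent tiles, no per-tile
statistical test: a DMR here is a 500 bp unit, which is also how loci
are numbered downstream (DMR1, DMR2, ...).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CpGCallTable, IntervalSet, SampleSheet

DEFAULT_TILE_SIZE = 500
DEFAULT_MIN_CPGS = 5
DEFAULT_DELTA = 0.15
DEFAULT_MIN_COV = 3


def build_tile_grid(chrom_lengths: Mapping[str, int],
                    tile_size: int = DEFAULT_TILE_SIZE) -> pd.DataFrame:
    """Non-overlapping tiles [0,ts), [ts,2ts), ... per chromosome.

    The trailing partial tile is dropped.  Returns a DataFrame with
    columns chrom/start/end indexed by ``"chrom:start-end"`` tile ids.
    """
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    frames = []
    for chrom in sorted(chrom_lengths):
        n = chrom_lengths[chrom] // tile_size
        starts = np.arange(n, dtype=np.int64) * tile_size
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                    "end": starts + tile_size}))
    tiles = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=["chrom", "start", "end"])
    tiles.index = pd.Index(
        [f"{c}:{s}-{e}" for c, s, e in tiles.itertuples(index=False)], name="tile_id")
    return tiles


@dataclass
class TileMatrix:
    """Tiles x samples methylation fractions with covered-CpG counts.

    ``values``: float in [0,1] or NaN for tiles with no contributing
    CpGs; ``cpg_count``: number of CpGs that contributed to each value.
    Both are indexed by tile id with one column per sample.
    """

    tiles: pd.DataFrame
    values: pd.DataFrame
    cpg_count: pd.DataFrame
    tile_size: int = DEFAULT_TILE_SIZE

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def restrict(self, tile_ids: Sequence[str]) -> "TileMatrix":
        tile_ids = [t for t in tile_ids if t in self.values.index]
        return TileMatrix(self.tiles.loc[tile_ids], self.values.loc[tile_ids],
                          self.cpg_count.loc[tile_ids], self.tile_size)

    def select_samples(self, sample_ids: Sequence[str]) -> "TileMatrix":
        return TileMatrix(self.tiles, self.values[list(sample_ids)],
                          self.cpg_count[list(sample_ids)], self.tile_size)


def tile_methylation(calls: CpGCallTable, tiles: pd.DataFrame,
                     min_cov_per_cpg: int = DEFAULT_MIN_COV,
                     tile_size: int | None = None) -> tuple[pd.Series, pd.Series]:
    """One TileMatrix column: coverage-weighted methylation per tile.

    Per tile, over CpGs with total >= ``min_cov_per_cpg``:
    value = sum(meth) / sum(total); cpg_count = number of contributing
    CpGs.  Tiles with no contributing CpG get NaN / 0.
    """
    if tile_size is None:
        tile_size = int(tiles["end"].iloc[0] - tiles["start"].iloc[0]) if len(tiles) else DEFAULT_TILE_SIZE
    df = calls.calls
    df = df[df["total"] >= min_cov_per_cpg]
    key = df["chrom"].astype(str) + ":" + (df["pos"] // tile_size * tile_size).astype(str)
    agg = df.groupby(key.values).agg(meth=("meth", "sum"), total=("total", "sum"),
                                     n=("pos", "size"))
    tile_key = tiles["chrom"].astype(str) + ":" + tiles["start"].astype(str)
    agg = agg.reindex(tile_key.values)
    values = pd.Series(agg["meth"].values / agg["total"].values,
                       index=tiles.index, name=calls.sample_id)
    counts = pd.Series(np.nan_to_num(agg["n"].values).astype(np.int64),
                       index=tiles.index, name=calls.sample_id)
    return values, counts


def build_tile_matrix(tables: Sequence[CpGCallTable], tiles: pd.DataFrame,
                      min_cov_per_cpg: int = DEFAULT_MIN_COV) -> TileMatrix:
    """Stack :func:`tile_methylation` columns for a cohort."""
    vals, counts = {}, {}
    for t in tables:
        v, c = tile_methylation(t, tiles, min_cov_per_cpg)
        vals[t.sample_id] = v
        counts[t.sample_id] = c
    tile_size = int(tiles["end"].iloc[0] - tiles["start"].iloc[0]) if len(tiles) else DEFAULT_TILE_SIZE
    return TileMatrix(tiles, pd.DataFrame(vals), pd.DataFrame(counts), tile_size)


def population_means(tm: TileMatrix, sheet: SampleSheet,
                     group_by: Sequence[str] = ("tissue", "lineage", "cd69"),
                     mode: str = "strict") -> TileMatrix:
    """Aggregate replicate samples into population groups.

    Group value is the unweighted mean of replicate tile values (pooled
    samples count as one replicate; their pooling already averaged
    donors).  Group cpg_count is the minimum over replicates.  In
    ``strict`` mode (default) the group value is missing if any
    replicate is missing; in ``lenient`` mode only if all are.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown mode {mode!r}")
    meta = sheet.samples.set_index("sample_id")
    missing = [s for s in tm.sample_ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples absent from sheet: {missing}")
    groups: dict[str, list[str]] = {}
    for sid in tm.sample_ids:
        key = "/".join(str(meta.loc[sid, g]) for g in group_by)
        groups.setdefault(key, []).append(sid)
    vals, counts = {}, {}
    for key, sids in sorted(groups.items()):
        sub = tm.values[sids]
        if mode == "strict":
            v = sub.mean(axis=1)
            v[sub.isna().any(axis=1)] = np.nan
        else:
            v = sub.mean(axis=1)            # skips NaN; all-NaN -> NaN
        vals[key] = v
        counts[key] = tm.cpg_count[sids].min(axis=1)
    return TileMatrix(tm.tiles, pd.DataFrame(vals), pd.DataFrame(counts), tm.tile_size)


def call_dmrs_pairwise(pops: TileMatrix, pop_a: str, pop_b: str,
                       min_cpgs: int = DEFAULT_MIN_CPGS,
                       delta: float = DEFAULT_DELTA) -> pd.DataFrame:
    """Tiles differentially methylated between two population groups.

    A tile passes iff both group values are present, both group
    cpg_counts are >= ``min_cpgs``, and |mean_a - mean_b| >= ``delta``.
    Returns chrom/start/end/diff (signed, mean_a - mean_b) indexed by
    tile id, in genomic order.
    """
    for p in (pop_a, pop_b):
        if p not in pops.values.columns:
            raise KeyError(f"population {p!r} not in matrix")
    a, b = pops.values[pop_a], pops.values[pop_b]
    ca, cb = pops.cpg_count[pop_a], pops.cpg_count[pop_b]
    diff = a - b
    mask = a.notna() & b.notna() & (ca >= min_cpgs) & (cb >= min_cpgs) & (diff.abs() >= delta)
    out = pops.tiles.loc[mask.values].copy()
    out["diff"] = diff[mask.values]
    return out


@dataclass
class DMRSet:
    """Compiled DMRs of one lineage x CD69 subset.

    ``dmrs``: chrom/start/end/max_abs_diff plus one signed-difference
    column ``diff_A_vs_B`` per pairwise comparison (NaN where the tile
    did not pass that pair) and ``populations_passing`` (list of
    (A, B) tuples), indexed by tile id in genomic order.
    """

    subset: tuple[str, str] | None
    dmrs: pd.DataFrame

    def __len__(self) -> int:
        return len(self.dmrs)

    @property
    def tile_ids(self) -> list[str]:
        return list(self.dmrs.index)

    def to_interval_set(self, name: str = "DMRs") -> IntervalSet:
        df = self.dmrs[["chrom", "start", "end"]].copy()
        df["label"] = self.dmrs.index
        df["score"] = (1000 * self.dmrs["max_abs_diff"]).round().astype(int).clip(0, 1000)
        return IntervalSet(name, df.reset_index(drop=True))


def compile_dmr_set(pairwise: Mapping[tuple[str, str], pd.DataFrame],
                    subset: tuple[str, str] | None = None) -> DMRSet:
    """Union of tiles passing in at least one pairwise comparison."""
    all_ids: set[str] = set()
    for res in pairwise.values():
        all_ids.update(res.index)
    frames = []
    for (a, b), res in pairwise.items():
        col = res["diff"].rename(f"diff_{a}_vs_{b}")
        frames.append(col)
    if not all_ids:
        cols = ["chrom", "start", "end", "max_abs_diff", "populations_passing"]
        cols += [f.name for f in frames]
        return DMRSet(subset, pd.DataFrame(columns=cols))
    coords = pd.concat([res[["chrom", "start", "end"]] for res in pairwise.values()])
    coords = coords[~coords.index.duplicated()]
    diffs = pd.concat(frames, axis=1).reindex(coords.index)
    out = coords.copy()
    out["max_abs_diff"] = diffs.abs().max(axis=1)
    passing = []
    pairs = list(pairwise)
    for tid in out.index:
        passing.append([p for p, res in pairwise.items() if tid in res.index])
    out["populations_passing"] = passing
    out = pd.concat([out, diffs], axis=1)
    out = out.sort_values(["chrom", "start"], kind="mergesort")
    return DMRSet(subset, out)


def compile_subset_dmrs(pops: TileMatrix, subset: tuple[str, str] | None = None,
                        min_cpgs: int = DEFAULT_MIN_CPGS,
                        delta: float = DEFAULT_DELTA) -> DMRSet:
    """All-pairs calling over the population columns, then compile."""
    cols = list(pops.values.columns)
    pairwise = {(a, b): call_dmrs_pairwise(pops, a, b, min_cpgs, delta)
                for a, b in combinations(cols, 2)}
    return compile_dmr_set(pairwise, subset)


def top_decile_dmrs(dmr_set: DMRSet) -> DMRSet:
    """DMRs at or above the 90th percentile of max_abs_diff (ties kept)."""
    if len(dmr_set) == 0:
        raise ValueError("top_decile_dmrs on an empty DMR set")
    cutoff = np.percentile(dmr_set.dmrs["max_abs_diff"].values, 90)
    keep = dmr_set.dmrs["max_abs_diff"] >= cutoff
    return DMRSet(dmr_set.subset, dmr_set.dmrs[keep])


def genome_fraction(dmr_set: DMRSet, chrom_lengths: Mapping[str, int]) -> float:
    """Total DMR bp over total genome bp."""
    genome = sum(chrom_lengths.values())
    if genome <= 0:
        raise ValueError("empty genome")
    if len(dmr_set) == 0:
        return 0.0
    span = (dmr_set.dmrs["end"] - dmr_set.dmrs["start"]).sum()
    return float(span) / float(genome)


def write_tile_matrix(tm: TileMatrix, path: str | Path, percent: bool = False) -> None:
    """Tile id rows x sample columns.

    ``percent=True`` writes the export convention (0-100 scale, one
    decimal); the default writes full-precision fractions so downstream
    stages can re-read without loss.
    """
    if percent:
        (100 * tm.values).round(1).to_csv(path, sep="\t", float_format="%.1f")
    else:
        tm.values.to_csv(path, sep="\t", float_format="%.12g")


def write_dmr_table(dmr_set: DMRSet, path: str | Path) -> None:
    """TSV with per-pair signed differences and compiled max_abs_diff."""
    df = dmr_set.dmrs.copy()
    if len(df):
        df["populations_passing"] = df["populations_passing"].map(
            lambda ps: ";".join(f"{a}|{b}" for a, b in ps))
    df.to_csv(path, sep="\t", float_format="%.12g", index_label="tile_id")
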