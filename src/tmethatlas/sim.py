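"""Synthetic methylome cohorts with planted ground truth.

Emulates the sampling design of an RRBS methylome atlas of human tissue
memory T cells: ~6 tissue groups x 2 lineages (CD4/CD8) x 2 CD69 states
with a few replicates each (7 for blood, which is CD69- only), a mix of
individual-donor and 3-donor pooled libraries, reduced-representation
capture of ~40% of CpGs, negative-binomial read depth, bimodal baseline
methylation, 500 bp tissue-specific planted DMRs, donor random effects
and partially methylated domains (PMDs) with tissue-shifted mean levels.

The generative model, per CpG and sample:

    m_true = clamp( baseline + dmr_effect + donor_offset , 0.01, 0.99 )

with the baseline replaced by the tissue's PMD level inside a PMD.
Baseline methylation is a 3-component Beta mixture (CpG-island-like low,
intermediate, background high) whose state is assigned per CpG cluster,
not per CpG, so 500 bp tiles are internally coherent.  Pooled samples
average the true methylation of their pool members before read
sampling.  Observed counts are meth ~ Binomial(total, m_true) with
total ~ NegBinomial(coverage_mean, dispersion), and only captured CpGs
are observed.  All randomness flows from a single integer seed;
identical seeds give identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .dmr import build_tile_grid
from .io import (CpGCallTable, Gene, GeneModel, IntervalSet, SampleSheet,
                 write_cpg_calls, write_gene_models, write_intervals,
                 write_sample_sheet)


class SimulationError(ValueError):
    """Config asks for an infeasible cohort."""


# Qualitative tissue pattern for PMD levels: lung/skin slightly eroded,
# intestine/spleen slightly above the bone-marrow/blood baseline.
_DEFAULT_PMD_LEVELS = {"Bm": 0.54, "In": 0.58, "Sp": 0.57,
                       "Lu": 0.48, "Sk": 0.47, "Bl": 0.54}


@dataclass
class SimConfig:
    """All knobs of the cohort generator; defaults are the study design."""

    seed: int = 0
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 300_000, "chr2": 200_000})

    # CpG landscape: clustered sites at ~1 per cpg_spacing_mean bp overall
    cpg_spacing_mean: float = 100.0
    cluster_size_mean: float = 12.0
    within_cluster_spacing_mean: float = 20.0

    # RRBS capture and sequencing depth
    capture_fraction: float = 0.4
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0       # NB size parameter r; var = m + m^2/r

    # baseline methylation mixture (low / intermediate / high)
    baseline_weights: tuple = (0.25, 0.15, 0.60)
    baseline_beta: tuple = ((2.0, 38.0), (8.0, 8.0), (38.0, 2.0))

    # cohort design
    tissues: tuple = ("Bm", "In", "Sp", "Lu", "Sk", "Bl")
    lineages: tuple = ("CD4", "CD8")
    cd69_states: tuple = ("pos", "neg")
    blood_tissue: str = "Bl"               # generated CD69- only, extra replicates
    donors_per_tissue: int = 3
    blood_replicates: int = 7
    pooled_fraction: float = 0.6
    pooled_pool_size: int = 3

    # planted tissue-specific DMRs
    n_planted_dmrs: int = 60
    dmr_width: int = 500
    dmr_delta: float = 0.4
    donor_sd: float = 0.05

    # PMDs
    pmd_count: int = 10
    pmd_len_range: tuple = (5_000, 20_000)
    pmd_level_by_group: dict | None = None

    # expression generator (negative methylation-expression coupling)
    n_genes: int = 60
    expr_intercept: float = 20.0
    expr_slope: float = 50.0
    expr_noise_sd: float = 5.0

    max_clamp_fraction: float = 0.02

    def __post_init__(self) -> None:
        for name in ("capture_fraction", "pooled_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationError(f"{name}={v} outside [0,1]")
        if not 0 <= self.dmr_delta <= 1:
            raise SimulationError("dmr_delta outside [0,1]")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise SimulationError("coverage parameters must be positive")
        if min(self.chrom_lengths.values()) < self.dmr_width:
            raise SimulationError("chromosome shorter than dmr_width")
        if self.pmd_level_by_group is None:
            levels = {}
            for i, t in enumerate(self.tissues):
                levels[t] = _DEFAULT_PMD_LEVELS.get(t, 0.55 - 0.015 * i)
            self.pmd_level_by_group = levels

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["chrom_lengths"] = dict(self.chrom_lengths)
        return json.dumps(d, indent=2, default=list)


@dataclass
class SimTruth:
    """Planted ground truth for recovery and calibration tests."""

    planted_dmrs: pd.DataFrame       # tile_id, chrom, start, end, tissue, direction, delta
    donor_effects: dict              # (donor, region class) -> offset
    pmds: IntervalSet
    pmd_levels: dict                 # tissue -> mean PMD methylation
    baseline: pd.DataFrame           # chrom, pos, cluster, state, base_mean, captured
    dmr_true_meth: pd.DataFrame      # planted tile x sample true regional methylation
    gene_dmr: dict                   # gene_id -> planted tile_id (for anchored genes)
    gene_meth: pd.DataFrame          # gene x sample regional true methylation
    clamp_fraction: float


_STATES = ("low", "mid", "high")


def _cpg_landscape(cfg: SimConfig, rng: np.random.Generator):
    """Clustered CpG positions with per-cluster baseline states."""
    frames = []
    cluster_id = 0
    for chrom in sorted(cfg.chrom_lengths):
        L = cfg.chrom_lengths[chrom]
        n_target = int(L / cfg.cpg_spacing_mean)
        n_clusters = max(1, round(n_target / cfg.cluster_size_mean))
        anchors = np.sort(rng.integers(0, L, size=n_clusters))
        for a in anchors:
            size = 1 + rng.poisson(max(cfg.cluster_size_mean - 1, 0))
            gaps = 2 + rng.exponential(max(cfg.within_cluster_spacing_mean - 2, 1), size=size)
            pos = a + np.cumsum(np.round(gaps)).astype(np.int64) - int(round(gaps[0]))
            pos = pos[pos < L]
            if len(pos) == 0:
                continue
            state = rng.choice(len(_STATES), p=cfg.baseline_weights)
            a_, b_ = cfg.baseline_beta[state]
            base = rng.beta(a_, b_, size=len(pos))
            frames.append(pd.DataFrame({"chrom": chrom, "pos": pos,
                                        "cluster": cluster_id,
                                        "state": _STATES[state],
                                        "base_mean": base}))
            cluster_id += 1
    df = pd.concat(frames, ignore_index=True)
    df = df.drop_duplicates(["chrom", "pos"]).sort_values(["chrom", "pos"])
    return df.reset_index(drop=True)


def _capture(df: pd.DataFrame, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """RRBS capture at the cluster level, hitting ``fraction`` of CpGs.

    Whole clusters are captured (RRBS fragments cover CpG-dense runs);
    clusters are taken in random order until the cumulative CpG count
    reaches the target, so the realised fraction is within one cluster
    of the requested one.
    """
    clusters = df["cluster"].values
    ids, counts = np.unique(clusters, return_counts=True)
    order = rng.permutation(len(ids))
    target = fraction * len(df)
    chosen = set()
    got = 0
    for k in order:
        if got >= target:
            break
        chosen.add(ids[k])
        got += counts[k]
    return np.isin(clusters, list(chosen))


def _place_pmds(cfg: SimConfig, rng: np.random.Generator) -> IntervalSet:
    """Non-overlapping PMD blocks, rejection-sampled per chromosome."""
    rows = []
    chroms = sorted(cfg.chrom_lengths)
    lens = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    placed: dict[str, list] = {c: [] for c in chroms}
    attempts = 0
    while len(rows) < cfg.pmd_count and attempts < 100 * cfg.pmd_count:
        attempts += 1
        c = chroms[rng.choice(len(chroms), p=lens / lens.sum())]
        L = cfg.chrom_lengths[c]
        width = int(rng.integers(cfg.pmd_len_range[0], cfg.pmd_len_range[1] + 1))
        if width >= L:
            continue
        start = int(rng.integers(0, L - width))
        end = start + width
        if any(start < e and s < end for s, e in placed[c]):
            continue
        placed[c].append((start, end))
        rows.append((c, start, end))
    rows.sort()
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["label"] = [f"PMD{i + 1:03d}" for i in range(len(df))]
    df["score"] = 0
    return IntervalSet("PMDs", df)


def _interval_mask(pos_by_chrom, iset: IntervalSet, index_count: int) -> np.ndarray:
    """Boolean mask over CpGs lying inside any interval of the set."""
    mask = np.zeros(index_count, dtype=bool)
    for chrom, (pos, idx) in pos_by_chrom.items():
        sub = iset.intervals[iset.intervals["chrom"] == chrom]
        for s, e in sub[["start", "end"]].itertuples(index=False):
            lo = np.searchsorted(pos, s, side="left")
            hi = np.searchsorted(pos, e, side="left")
            mask[idx[lo:hi]] = True
    return mask


def _build_samples(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """The cohort design table (one row per library)."""
    rows = []
    for lineage in cfg.lineages:
        for cd69 in cfg.cd69_states:
            for tissue in cfg.tissues:
                if tissue == cfg.blood_tissue and cd69 == "pos":
                    continue        # circulating blood Tm are >98% CD69-
                n_rep = cfg.blood_replicates if tissue == cfg.blood_tissue \
                    else cfg.donors_per_tissue
                for r in range(n_rep):
                    sid = f"{tissue}_{lineage}_{cd69}_r{r + 1}"
                    pooled = bool(rng.random() < cfg.pooled_fraction)
                    if pooled:
                        donors = [f"P_{sid}_{j + 1}" for j in range(cfg.pooled_pool_size)]
                    else:
                        donors = [f"D{r + 1:02d}"]
                    rows.append((sid, tissue, lineage, cd69, donors, pooled))
    return pd.DataFrame(rows, columns=["sample_id", "tissue", "lineage",
                                       "cd69", "donors", "pooled"])


def _plant_dmrs(cfg: SimConfig, base_df: pd.DataFrame, captured: np.ndarray,
                pmd_mask: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Pick planted tiles: captured, CpG-rich, outside PMDs.

    DMRs are planted only where RRBS can see them — at least 5 captured
    CpGs in the tile — because unobservable ground truth would make
    recovery rates meaningless.  Direction adapts to the local baseline
    (hypomethylation from high baselines, hyper from low) so effects
    stay inside [0, 1].
    """
    tiles = build_tile_grid(cfg.chrom_lengths, cfg.dmr_width)
    key = (base_df["chrom"].astype(str) + ":"
           + (base_df["pos"] // cfg.dmr_width * cfg.dmr_width).astype(str))
    ok = captured & ~pmd_mask
    grp = pd.DataFrame({"key": key.values, "ok": ok, "base": base_df["base_mean"].values})
    agg = grp[grp["ok"]].groupby("key").agg(n=("base", "size"), mean=("base", "mean"))
    # exclude tiles containing any PMD CpG entirely
    bad = set(grp.loc[pmd_mask, "key"])
    tile_key = tiles["chrom"].astype(str) + ":" + tiles["start"].astype(str)
    usable = tile_key.isin(set(agg[agg["n"] >= 5].index) - bad)
    candidates = tiles[usable.values]
    if len(candidates) < cfg.n_planted_dmrs:
        raise SimulationError(
            f"only {len(candidates)} plantable tiles for {cfg.n_planted_dmrs} DMRs")
    pick = rng.choice(len(candidates), size=cfg.n_planted_dmrs, replace=False)
    chosen = candidates.iloc[np.sort(pick)]
    tissues = [cfg.tissues[i % len(cfg.tissues)]
               for i in rng.permutation(cfg.n_planted_dmrs)]
    rows = []
    for (tid, row), tissue in zip(chosen.iterrows(), tissues):
        k = f"{row['chrom']}:{row['start']}"
        mean = agg.loc[k, "mean"]
        direction = "hypo" if mean >= 0.5 else "hyper"
        delta = -cfg.dmr_delta if direction == "hypo" else cfg.dmr_delta
        rows.append((tid, row["chrom"], int(row["start"]), int(row["end"]),
                     tissue, direction, delta))
    out = pd.DataFrame(rows, columns=["tile_id", "chrom", "start", "end",
                                      "tissue", "direction", "delta"])
    return out.set_index("tile_id")


def _make_genes(cfg: SimConfig, planted: pd.DataFrame,
                rng: np.random.Generator) -> tuple[GeneModel, dict]:
    """Gene models, half anchored to planted DMRs (promoter or intron)."""
    genes: list[Gene] = []
    gene_dmr: dict[str, str] = {}
    chrom_lengths = cfg.chrom_lengths
    n_anchored = min(cfg.n_genes // 2, len(planted))
    anchor_rows = list(planted.iloc[:n_anchored].iterrows())
    gi = 0

    def _fits(chrom, lo, hi):
        return lo >= 0 and hi <= chrom_lengths[chrom]

    for j, (tid, row) in enumerate(anchor_rows):
        chrom, ts = row["chrom"], int(row["start"])
        mid = ts + cfg.dmr_width // 2
        strand = "+" if rng.random() < 0.5 else "-"
        if j % 2 == 0:  # promoter-anchored: TSS within 1 kb of the DMR midpoint
            tss = mid + int(rng.integers(-1000, 1001))
            if strand == "+":
                exons = [(tss, tss + 400), (tss + 900, tss + 1300), (tss + 2000, tss + 2600)]
            else:
                exons = [(tss - 2600, tss - 2000), (tss - 1300, tss - 900), (tss - 400, tss + 1)]
        else:           # intron-anchored: first intron spans the tile
            if strand == "+":
                exons = [(ts - 800, ts - 300), (ts + 600, ts + 900), (ts + 1500, ts + 2000)]
            else:
                exons = [(ts - 1000, ts - 500), (ts + 600, ts + 900), (ts + 1500, ts + 2000)]
        lo, hi = exons[0][0], exons[-1][1]
        if not _fits(chrom, lo, hi):
            continue
        gid = f"G{gi + 1:04d}"
        utr5 = [(exons[0][0], exons[0][0] + 100)] if strand == "+" else \
            [(exons[-1][1] - 100, exons[-1][1])]
        utr3 = [(exons[-1][1] - 100, exons[-1][1])] if strand == "+" else \
            [(exons[0][0], exons[0][0] + 100)]
        genes.append(Gene(gid, chrom, strand, exons, utr5, utr3))
        gene_dmr[gid] = tid
        gi += 1

    chroms = sorted(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    tries = 0
    while gi < cfg.n_genes and tries < 50 * cfg.n_genes:
        tries += 1
        chrom = chroms[rng.choice(len(chroms), p=lens / lens.sum())]
        start = int(rng.integers(0, max(chrom_lengths[chrom] - 6000, 1)))
        strand = "+" if rng.random() < 0.5 else "-"
        exons = [(start, start + 500), (start + 1500, start + 2000),
                 (start + 3500, start + 4200)]
        if not _fits(chrom, exons[0][0], exons[-1][1]):
            continue
        gid = f"G{gi + 1:04d}"
        utr5 = [(exons[0][0], exons[0][0] + 120)] if strand == "+" else \
            [(exons[-1][1] - 120, exons[-1][1])]
        utr3 = [(exons[-1][1] - 120, exons[-1][1])] if strand == "+" else \
            [(exons[0][0], exons[0][0] + 120)]
        genes.append(Gene(gid, chrom, strand, exons, utr5, utr3))
        gi += 1
    return GeneModel(genes), gene_dmr


def simulate_cohort(cfg: SimConfig):
    """Generate a cohort.

    Returns ``(tables, sheet, genes, truth)``: a dict of sample_id ->
    CpGCallTable, the SampleSheet, a GeneModel with half the genes
    anchored to planted DMRs, and the SimTruth.
    """
    land_rng = np.random.default_rng([cfg.seed, 0])

    base_df = _cpg_landscape(cfg, land_rng)
    captured = _capture(base_df, cfg.capture_fraction, land_rng)
    pmds = _place_pmds(cfg, land_rng)

    pos_by_chrom = {}
    for chrom, sub in base_df.groupby("chrom", sort=False):
        pos_by_chrom[chrom] = (sub["pos"].values, sub.index.values)
    pmd_mask = _interval_mask(pos_by_chrom, pmds, len(base_df))

    planted = _plant_dmrs(cfg, base_df, captured, pmd_mask, land_rng)
    design = _build_samples(cfg, land_rng)
    genes, gene_dmr = _make_genes(cfg, planted, land_rng)

    # donor random effects: one offset per donor per region class
    classes = _STATES + ("pmd",)
    donors = sorted({d for ds in design["donors"] for d in ds})
    donor_effects = {(d, c): float(land_rng.normal(0.0, cfg.donor_sd))
                     for d in donors for c in classes}

    # per-CpG static pieces
    base = base_df["base_mean"].values.copy()
    state = base_df["state"].values
    class_idx = np.where(pmd_mask, "pmd", state)
    dmr_effect_by_tissue: dict[str, np.ndarray] = {
        t: np.zeros(len(base_df)) for t in cfg.tissues}
    tile_members: dict[str, np.ndarray] = {}
    for tid, row in planted.iterrows():
        chrom = row["chrom"]
        pos, idx = pos_by_chrom[chrom]
        lo = np.searchsorted(pos, row["start"], side="left")
        hi = np.searchsorted(pos, row["end"], side="left")
        members = idx[lo:hi]
        tile_members[tid] = members[captured[members]]
        dmr_effect_by_tissue[row["tissue"]][members] += row["delta"]
    pmd_level_arr = {t: np.where(pmd_mask, cfg.pmd_level_by_group[t], 0.0)
                     for t in cfg.tissues}

    cap_idx = np.flatnonzero(captured)
    n_cap = len(cap_idx)
    chrom_cap = base_df["chrom"].values[cap_idx]
    pos_cap = base_df["pos"].values[cap_idx]

    clamped = 0
    total_vals = 0

    def true_meth(tissue: str, donor: str) -> np.ndarray:
        m = base.copy()
        m[pmd_mask] = pmd_level_arr[tissue][pmd_mask]
        m += dmr_effect_by_tissue[tissue]
        off = np.array([donor_effects[(donor, c)] for c in classes])
        # donor offsets attenuate toward the boundaries of the unit
        # interval (full strength at m=0.5, zero at 0/1), so
        # inter-individual variability lives where methylation is
        # actually variable and effects stay inside [0, 1]
        scale = np.clip(2.0 * np.minimum(m, 1.0 - m), 0.0, 1.0)
        m += np.select([class_idx == c for c in classes], off) * scale
        return m

    tables: dict[str, CpGCallTable] = {}
    dmr_meth_rows: dict[str, dict] = {tid: {} for tid in planted.index}
    p_nb = cfg.coverage_dispersion / (cfg.coverage_dispersion + cfg.coverage_mean)

    for i, srow in design.iterrows():
        sid = srow["sample_id"]
        profiles = [true_meth(srow["tissue"], d) for d in srow["donors"]]
        m = np.mean(profiles, axis=0)       # pooling averages donors
        raw = m.copy()
        m = np.clip(m, 0.01, 0.99)
        clamped += int(np.sum(np.abs(raw - m) > 0.01))
        total_vals += len(m)

        srng = np.random.default_rng([cfg.seed, 1, i])
        total = srng.negative_binomial(cfg.coverage_dispersion, p_nb, size=n_cap)
        keep = total > 0
        meth = srng.binomial(total[keep], m[cap_idx][keep])
        tables[sid] = CpGCallTable(sid, pd.DataFrame({
            "chrom": chrom_cap[keep], "pos": pos_cap[keep],
            "meth": meth, "total": total[keep]}))
        for tid, members in tile_members.items():
            dmr_meth_rows[tid][sid] = float(np.mean(m[members])) if len(members) else np.nan

    clamp_fraction = clamped / max(total_vals, 1)
    if clamp_fraction > cfg.max_clamp_fraction:
        raise SimulationError(
            f"{100 * clamp_fraction:.2f}% of methylation values clamped beyond "
            f"tolerance; effects push methylation outside [0, 1]")

    sheet = SampleSheet(design)
    dmr_true_meth = pd.DataFrame.from_dict(dmr_meth_rows, orient="index")
    dmr_true_meth = dmr_true_meth.reindex(index=planted.index,
                                          columns=design["sample_id"])

    # per-gene regional true methylation (promoter region of the anchor DMR
    # for anchored genes; static promoter baseline otherwise)
    gm_rows = {}
    for g in genes:
        if g.gene_id in gene_dmr:
            gm_rows[g.gene_id] = dmr_true_meth.loc[gene_dmr[g.gene_id]]
        else:
            s, e = g.promoter(1000)
            pos, idx = pos_by_chrom.get(g.chrom, (np.array([]), np.array([])))
            lo = np.searchsorted(pos, s, side="left")
            hi = np.searchsorted(pos, e, side="left")
            val = float(np.mean(base[idx[lo:hi]])) if hi > lo else 0.5
            gm_rows[g.gene_id] = pd.Series(val, index=design["sample_id"])
    gene_meth = pd.DataFrame(gm_rows).T
    gene_meth = gene_meth[design["sample_id"]]

    baseline = base_df.copy()
    baseline["captured"] = captured
    truth = SimTruth(planted_dmrs=planted, donor_effects=donor_effects,
                     pmds=pmds, pmd_levels=dict(cfg.pmd_level_by_group),
                     baseline=baseline, dmr_true_meth=dmr_true_meth,
                     gene_dmr=gene_dmr, gene_meth=gene_meth,
                     clamp_fraction=clamp_fraction)
    return tables, sheet, genes, truth


def simulate_expression(truth: SimTruth, cfg: SimConfig) -> pd.DataFrame:
    """Per-gene, per-sample linear-scale expression (CPM-like units).

    expression = a + b * (1 - regional methylation) + N(0, noise_sd):
    demethylation raises expression, so regressing expression on
    methylation recovers a slope of -b.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    m = truth.gene_meth.values
    noise = rng.normal(0.0, cfg.expr_noise_sd, size=m.shape)
    expr = cfg.expr_intercept + cfg.expr_slope * (1.0 - m) + noise
    return pd.DataFrame(expr, index=truth.gene_meth.index,
                        columns=truth.gene_meth.columns)


def write_cohort(outdir: str | Path, tables: Mapping[str, CpGCallTable],
                 sheet: SampleSheet, genes: GeneModel, truth: SimTruth,
                 cfg: SimConfig, expression: pd.DataFrame | None = None) -> dict:
    """Write every cohort artifact as plain text; returns a manifest dict."""
    outdir = Path(outdir)
    calls_dir = outdir / "calls"
    calls_dir.mkdir(parents=True, exist_ok=True)
    for sid, table in tables.items():
        write_cpg_calls(table, calls_dir / f"{sid}.cov")
    write_sample_sheet(sheet, outdir / "sample_sheet.tsv")
    write_gene_models(genes, outdir / "genes.bed12")
    write_intervals(truth.pmds, outdir / "pmds.bed")
    planted = truth.planted_dmrs.reset_index()
    planted.to_csv(outdir / "truth_dmrs.tsv", sep="\t", index=False,
                   float_format="%.6g")
    dmr_bed = IntervalSet("planted", pd.DataFrame({
        "chrom": planted["chrom"], "start": planted["start"],
        "end": planted["end"], "label": planted["tile_id"],
        "score": (1000 * planted["delta"].abs()).round().astype(int)}))
    write_intervals(dmr_bed, outdir / "truth_dmrs.bed")
    (outdir / "sim_config.json").write_text(cfg.to_json())
    if expression is not None:
        expression.to_csv(outdir / "expression.tsv", sep="\t",
                          float_format="%.6g", index_label="gene_id")
    return {"calls_dir": str(calls_dir), "n_samples": len(tables),
            "n_planted_dmrs": len(truth.planted_dmrs),
            "clamp_fraction": truth.clamp_fraction}
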