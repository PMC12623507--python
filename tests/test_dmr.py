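"""Tiling, coverage-weighted tile methylation and the DMR rule."""

import numpy as np
import pandas as pd
import pytest

from tmethatlas import (CpGCallTable, SampleSheet, SimConfig, build_tile_grid,
                        build_tile_matrix, call_dmrs_pairwise, compile_dmr_set,
                        compile_subset_dmrs, genome_fraction, population_means,
                        simulate_cohort, tile_methylation, top_decile_dmrs)
from tmethatlas.dmr import DMRSet, TileMatrix

from conftest import make_tile_matrix


def calls_from(pos_meth_total, chrom="chr1", sample="s"):
    pos, meth, total = zip(*pos_meth_total)
    return CpGCallTable(sample, pd.DataFrame(
        {"chrom": chrom, "pos": list(pos), "meth": list(meth), "total": list(total)}))


class TestTileGrid:
    @pytest.mark.parametrize("length,n", [(1250, 2), (499, 0), (1_000_000, 2000)])
    def test_tile_count(self, length, n):
        tiles = build_tile_grid({"chr1": length}, 500)
        assert len(tiles) == n

    def test_tiles_disjoint_and_covering(self):
        tiles = build_tile_grid({"chr1": 1_000_000}, 500)
        assert tiles["start"].iloc[0] == 0
        assert tiles["end"].iloc[-1] == 1_000_000
        assert (tiles["start"].values[1:] == tiles["end"].values[:-1]).all()


class TestTileMethylation:
    def test_weighted_formula(self):
        calls = calls_from([(10, 7, 7), (90, 0, 5)])
        tiles = build_tile_grid({"chr1": 500}, 500)
        v, c = tile_methylation(calls, tiles)
        assert v.iloc[0] == pytest.approx(7 / 12)
        assert c.iloc[0] == 2

    def test_coverage_floor(self):
        calls = calls_from([(10, 1, 2)])
        tiles = build_tile_grid({"chr1": 500}, 500)
        v, c = tile_methylation(calls, tiles, min_cov_per_cpg=3)
        assert np.isnan(v.iloc[0]) and c.iloc[0] == 0

    def test_matches_brute_force_loop_exactly(self):
        rng = np.random.default_rng(3)
        n = 400
        pos = np.sort(rng.choice(50_000, size=n, replace=False))
        total = rng.integers(1, 50, size=n)
        meth = rng.binomial(total, rng.beta(0.5, 0.5, size=n))
        calls = calls_from(list(zip(pos, meth, total)))
        tiles = build_tile_grid({"chr1": 50_000}, 500)
        v, c = tile_methylation(calls, tiles, min_cov_per_cpg=3)
        for tid, row in tiles.iterrows():
            sm = st = k = 0
            for p, m, t in zip(pos, meth, total):
                if row["start"] <= p < row["end"] and t >= 3:
                    sm += m
                    st += t
                    k += 1
            if k == 0:
                assert np.isnan(v.loc[tid])
            else:
                assert v.loc[tid] == sm / st       # identical integer ratio
            assert c.loc[tid] == k


def _sheet_for(samples, tissues):
    return SampleSheet(pd.DataFrame({
        "sample_id": samples, "tissue": tissues,
        "lineage": "CD4", "cd69": "pos",
        "donors": [[f"D{i}"] for i in range(len(samples))],
        "pooled": False}))


class TestPopulationMeans:
    def test_unweighted_mean(self):
        tm = make_tile_matrix({"a": [0.2], "b": [0.4]})
        sheet = _sheet_for(["a", "b"], ["Bm", "Bm"])
        pops = population_means(tm, sheet, group_by=("tissue",))
        assert pops.values.loc[tm.values.index[0], "Bm"] == pytest.approx(0.3)

    def test_strict_mode_propagates_missing(self):
        tm = make_tile_matrix({"a": [0.2], "b": [np.nan]})
        sheet = _sheet_for(["a", "b"], ["Bm", "Bm"])
        strict = population_means(tm, sheet, group_by=("tissue",))
        assert np.isnan(strict.values.iloc[0, 0])
        lenient = population_means(tm, sheet, group_by=("tissue",), mode="lenient")
        assert lenient.values.iloc[0, 0] == pytest.approx(0.2)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(4)
        vals = {s: rng.random(20) for s in ["a", "b", "c", "d", "e", "f"]}
        for s in vals:
            vals[s][rng.random(20) < 0.1] = np.nan
        tm = make_tile_matrix(vals)
        tissues = ["Bm", "Bm", "Sk", "Sk", "Sk", "Lu"]
        sheet = _sheet_for(list(vals), tissues)
        pops = population_means(tm, sheet, group_by=("tissue",))
        for i in range(20):
            for tissue in set(tissues):
                members = [s for s, t in zip(vals, tissues) if t == tissue]
                xs = [vals[s][i] for s in members]
                expect = np.nan if any(np.isnan(x) for x in xs) else np.mean(xs)
                got = pops.values.iloc[i][tissue]
                assert (np.isnan(got) and np.isnan(expect)) or got == pytest.approx(expect)


class TestDMRRule:
    def test_basic_call_and_sign(self):
        tm = make_tile_matrix({"A": [0.10], "B": [0.30]},
                              counts={"A": [6], "B": [6]})
        res = call_dmrs_pairwise(tm, "A", "B")
        assert len(res) == 1
        assert res["diff"].iloc[0] == pytest.approx(-0.20)

    def test_threshold_is_inclusive_at_15_points(self):
        tm = make_tile_matrix({"A": [0.10, 0.10], "B": [0.24, 0.25]},
                              counts={"A": [6, 6], "B": [6, 6]})
        res = call_dmrs_pairwise(tm, "A", "B")
        assert list(res.index) == [tm.values.index[1]]    # 0.14 < 0.15 <= 0.15

    def test_min_cpgs_in_both_populations(self):
        tm = make_tile_matrix({"A": [0.1], "B": [0.5]},
                              counts={"A": [4], "B": [20]})
        assert len(call_dmrs_pairwise(tm, "A", "B", min_cpgs=5)) == 0
        assert len(call_dmrs_pairwise(tm, "A", "B", min_cpgs=4)) == 1

    def test_symmetry_negates_diffs(self):
        rng = np.random.default_rng(5)
        tm = make_tile_matrix({"A": rng.random(50), "B": rng.random(50)})
        ab = call_dmrs_pairwise(tm, "A", "B")
        ba = call_dmrs_pairwise(tm, "B", "A")
        assert list(ab.index) == list(ba.index)
        assert np.allclose(ab["diff"].values, -ba["diff"].values)

    def test_sample_permutation_and_chrom_relabel_invariance(self, flat_cohort):
        cfg, tables, sheet, genes, truth = flat_cohort
        tiles = build_tile_grid(cfg.chrom_lengths, 500)
        tabs = list(tables.values())
        tm1 = build_tile_matrix(tabs, tiles)
        tm2 = build_tile_matrix(tabs[::-1], tiles)
        pops1 = population_means(tm1, sheet, group_by=("tissue",))
        pops2 = population_means(tm2, sheet, group_by=("tissue",))
        d1 = compile_subset_dmrs(pops1)
        d2 = compile_subset_dmrs(pops2)
        assert d1.tile_ids == d2.tile_ids
        # chromosome relabeling maps tile ids consistently
        ren = []
        for t in tabs:
            c = t.calls.copy()
            c["chrom"] = c["chrom"].str.replace("chr1", "chrX")
            ren.append(CpGCallTable(t.sample_id, c))
        tilesX = build_tile_grid({"chrX": cfg.chrom_lengths["chr1"]}, 500)
        popsX = population_means(build_tile_matrix(ren, tilesX), sheet,
                                 group_by=("tissue",))
        dX = compile_subset_dmrs(popsX)
        assert [t.replace("chrX", "chr1") for t in dX.tile_ids] == d1.tile_ids


class TestCompile:
    def test_union_and_passing_pairs(self):
        tm = make_tile_matrix({"Bm": [0.1, 0.5], "Sk": [0.4, 0.5], "Lu": [0.1, 0.5]})
        pairwise = {
            ("Bm", "Sk"): call_dmrs_pairwise(tm, "Bm", "Sk"),
            ("Bm", "Lu"): call_dmrs_pairwise(tm, "Bm", "Lu"),
            ("Sk", "Lu"): call_dmrs_pairwise(tm, "Sk", "Lu"),
        }
        ds = compile_dmr_set(pairwise)
        assert len(ds) == 1
        row = ds.dmrs.iloc[0]
        assert set(row["populations_passing"]) == {("Bm", "Sk"), ("Sk", "Lu")}
        assert row["max_abs_diff"] == pytest.approx(0.3)

    def test_empty_compile(self):
        tm = make_tile_matrix({"A": [0.5], "B": [0.5]})
        ds = compile_dmr_set({("A", "B"): call_dmrs_pairwise(tm, "A", "B")})
        assert len(ds) == 0

    def test_null_cohort_yields_empty_set(self):
        cfg = SimConfig(seed=2, chrom_lengths={"chr1": 60_000},
                        lineages=("CD4",), cd69_states=("neg",),
                        donors_per_tissue=3, blood_replicates=3,
                        pooled_fraction=0.0, n_planted_dmrs=0, dmr_delta=0.0,
                        donor_sd=0.0, coverage_mean=200.0, pmd_count=0, n_genes=4)
        tables, sheet, genes, truth = simulate_cohort(cfg)
        tiles = build_tile_grid(cfg.chrom_lengths, 500)
        tm = build_tile_matrix(list(tables.values()), tiles)
        pops = population_means(tm, sheet, group_by=("tissue",))
        assert len(compile_subset_dmrs(pops)) == 0

    def test_false_positive_rate_decreases_with_coverage(self):
        counts = []
        for cov in (4.0, 12.0, 60.0):
            cfg = SimConfig(seed=7, chrom_lengths={"chr1": 120_000},
                            lineages=("CD4",), cd69_states=("neg",),
                            donors_per_tissue=2, blood_replicates=2,
                            pooled_fraction=0.0, n_planted_dmrs=0, dmr_delta=0.0,
                            donor_sd=0.0, coverage_mean=cov, pmd_count=0, n_genes=4)
            tables, sheet, genes, truth = simulate_cohort(cfg)
            tiles = build_tile_grid(cfg.chrom_lengths, 500)
            tm = build_tile_matrix(list(tables.values()), tiles, min_cov_per_cpg=2)
            pops = population_means(tm, sheet, group_by=("tissue",))
            counts.append(len(compile_subset_dmrs(pops)))
        assert counts[0] >= counts[1] >= counts[2]
        assert counts[0] > counts[2]


class TestTopDecileAndGenomeFraction:
    def _set(self, diffs):
        n = len(diffs)
        starts = np.arange(n) * 500
        df = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 500,
                           "max_abs_diff": diffs,
                           "populations_passing": [[("A", "B")]] * n},
                          index=[f"chr1:{s}-{s + 500}" for s in starts])
        return DMRSet(None, df)

    def test_distinct_diffs_keep_top(self):
        ds = self._set(np.linspace(0.15, 0.60, 10))
        top = top_decile_dmrs(ds)
        assert list(top.dmrs["max_abs_diff"]) == [0.60]

    def test_all_ties_all_kept(self):
        ds = self._set([0.3] * 7)
        assert len(top_decile_dmrs(ds)) == 7

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(6)
        diffs = rng.permutation(np.linspace(0.15, 0.9, 1000))  # distinct
        ds = self._set(diffs)
        top = top_decile_dmrs(ds)
        oracle = set(np.sort(diffs)[-100:])
        assert set(top.dmrs["max_abs_diff"]) == oracle

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            top_decile_dmrs(self._set([]))

    def test_genome_fraction(self):
        ds = self._set([0.3] * 10)
        assert genome_fraction(ds, {"chr1": 100_000}) == pytest.approx(0.05)
        assert genome_fraction(self._set([]), {"chr1": 100_000}) == 0.0

    def test_genome_fraction_equals_bp_sum(self):
        rng = np.random.default_rng(8)
        ds = self._set(rng.uniform(0.15, 0.9, size=37))
        bp = sum(e - s for s, e in ds.dmrs[["start", "end"]].itertuples(index=False))
        assert genome_fraction(ds, {"chr1": 2_000_000}) == bp / 2_000_000
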