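import numpy as np
import pandas as pd
import pytest

from tmethatlas import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-design cohort shared by read-only tests."""
    cfg = SimConfig(seed=11)
    tables, sheet, genes, truth = simulate_cohort(cfg)
    return cfg, tables, sheet, genes, truth


@pytest.fixture(scope="session")
def flat_cohort():
    """Small single-subset cohort: 6 tissues x 3 donors, no pooling.

    Blood is just another tissue here (CD69- subset), so every planted
    DMR is observable within the one subset.
    """
    cfg = SimConfig(seed=5, chrom_lengths={"chr1": 200_000},
                    lineages=("CD4",), cd69_states=("neg",),
                    donors_per_tissue=3, blood_replicates=3,
                    pooled_fraction=0.0, n_planted_dmrs=40,
                    pmd_count=4, n_genes=20)
    tables, sheet, genes, truth = simulate_cohort(cfg)
    return cfg, tables, sheet, genes, truth


def make_tile_matrix(values: dict, counts: dict | None = None, tile_size=500):
    """Hand-build a TileMatrix from {sample: [v...]} over chr1 tiles."""
    from tmethatlas import TileMatrix

    n = len(next(iter(values.values())))
    starts = np.arange(n) * tile_size
    tiles = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + tile_size})
    tiles.index = [f"chr1:{s}-{s + tile_size}" for s in starts]
    vals = pd.DataFrame(values, index=tiles.index, dtype=float)
    if counts is None:
        counts = {k: [10] * n for k in values}
    cnt = pd.DataFrame(counts, index=tiles.index)
    return TileMatrix(tiles, vals, cnt, tile_size)
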