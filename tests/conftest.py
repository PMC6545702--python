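import numpy as np
import pandas as pd
import pytest

import corsiv


def truth_region_table(sim, bm) -> pd.DataFrame:
    """Region table (with bin_ids into bm) for the generator's planted truth."""
    starts = bm.bins["start"].to_numpy()
    chroms = bm.bins["chrom"].to_numpy()
    ncpg = bm.bins["n_cpgs"].to_numpy()
    rows = []
    for r in sim.truth.itertuples():
        ids = np.flatnonzero((chroms == r.chrom) & (starts >= r.start) & (starts < r.end))
        rows.append(
            {
                "region_id": r.region_id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "cls": r.cls,
                "n_bins": len(ids),
                "n_cpgs": int(ncpg[ids].sum()),
                "bin_ids": ids,
            }
        )
    return pd.DataFrame(rows)


def overlap_any(row, calls: pd.DataFrame) -> bool:
    sub = calls[
        (calls["chrom"] == row.chrom)
        & (calls["start"] < row.end)
        & (calls["end"] > row.start)
    ]
    return len(sub) > 0


@pytest.fixture(scope="session")
def default_sim():
    """The default study conditions: 10 individuals x 3 tissues, 2 x 5 Mb,
    ~40x depth, 100 planted systemic regions + 200 tissue DMRs."""
    return corsiv.simulate_cohort(corsiv.SimConfig(seed=20250901))


@pytest.fixture(scope="session")
def default_bm(default_sim):
    return default_sim.bin_matrix()


@pytest.fixture(scope="session")
def default_screen(default_bm):
    return corsiv.CorsivScreen(default_bm).fit()


@pytest.fixture(scope="session")
def small_sim():
    cfg = corsiv.SimConfig(
        seed=11,
        chrom_sizes={"chr1": 400_000, "chr2": 400_000},
        n_systemic_genetic=8,
        n_systemic_stochastic=8,
        n_tissue_dmr=16,
    )
    return corsiv.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_bm(small_sim):
    return small_sim.bin_matrix()


@pytest.fixture(scope="session")
def small_screen(small_bm):
    return corsiv.CorsivScreen(small_bm).fit(n_perm=200, seed=5)
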