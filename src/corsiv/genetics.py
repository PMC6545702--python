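"""Genetic influence on region methylation.

Four complementary analyses: single-SNV mQTL regression near each called
region; pairwise donor concordance between methylation differences and
average local genotype differences; a read-depth vs methylation rank
correlation that flags copy-number-driven signals; and comparison of the
decay of methylation correlation with the decay of linkage disequilibrium in
the 20-kb flanks, which separates haplotype-driven regions from pure
epigenetic variation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .binmatrix import BinMatrix
from .io import genotype_matrix
from .screen import region_stats, _rowwise_pearson

log = logging.getLogger(__name__)


def ld_r2(g1, g2) -> float:
    """Composite LD: squared Pearson correlation of additive genotype
    dosages (pairwise-complete); NaN if either is constant."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = ~np.isnan(g1) & ~np.isnan(g2)
    if ok.sum() < 3:
        return float("nan")
    g1, g2 = g1[ok], g2[ok]
    if g1.std() == 0 or g2.std() == 0:
        return float("nan")
    return float(np.corrcoef(g1, g2)[0, 1] ** 2)


# ---------------------------------------------------------------------------
# mQTL


def mqtl_scan(
    corsivs: pd.DataFrame,
    pooled_means: np.ndarray,
    genotypes: pd.DataFrame,
    individuals: list[str],
    window: int = 10_000,
    beta_min: float = 10.0,
    r2_min: float = 0.5,
    q_max: float = 0.05,
):
    """Single-SNV mQTL scan over all called regions.

    For every SNV within ``window`` bp of a region boundary whose cohort
    genotypes include all three classes {0, 1, 2}, individual pooled region
    methylation (percent) is regressed on additive genotype by OLS.  The
    Benjamini-Hochberg correction is applied across the full region x SNV
    table; a region is mQTL-positive when its best SNV satisfies
    |beta| >= ``beta_min`` pp/allele, R^2 >= ``r2_min`` and q < ``q_max``.

    Returns ``(tests, per_region)``: the full test table and a per-region
    summary (best SNV by R^2, call in {positive, negative, non_informative}).
    """
    G = genotype_matrix(genotypes, individuals)
    gpos = genotypes["pos"].to_numpy()
    gchrom = genotypes["chrom"].to_numpy()
    rows = []
    for k, reg in corsivs.reset_index(drop=True).iterrows():
        y = pooled_means[k]
        sel = (
            (gchrom == reg["chrom"])
            & (gpos >= reg["start"] - window)
            & (gpos < reg["end"] + window)
        )
        informative = False
        for j in np.flatnonzero(sel):
            g = G[j]
            ok = ~np.isnan(g) & ~np.isnan(y)
            if ok.sum() < 3:
                continue
            if not {0.0, 1.0, 2.0}.issubset(set(g[ok])):
                continue
            informative = True
            res = stats.linregress(g[ok], y[ok])
            rows.append(
                {
                    "corsiv_id": reg["region_id"],
                    "snv_id": genotypes["snv_id"].iloc[j],
                    "beta": res.slope,
                    "r2": res.rvalue**2,
                    "p": res.pvalue,
                }
            )
        if not informative:
            rows.append(
                {
                    "corsiv_id": reg["region_id"],
                    "snv_id": None,
                    "beta": np.nan,
                    "r2": np.nan,
                    "p": np.nan,
                }
            )
    tests = pd.DataFrame(rows, columns=["corsiv_id", "snv_id", "beta", "r2", "p"])
    valid = tests["p"].notna()
    tests["q"] = np.nan
    if valid.any():
        tests.loc[valid, "q"] = multipletests(
            tests.loc[valid, "p"].to_numpy(), method="fdr_bh"
        )[1]
    tests["positive"] = (
        valid
        & (tests["beta"].abs() >= beta_min)
        & (tests["r2"] >= r2_min)
        & (tests["q"] < q_max)
    )

    summaries = []
    for cid, grp in tests.groupby("corsiv_id", sort=False):
        if grp["p"].isna().all():
            summaries.append(
                {"corsiv_id": cid, "call": "non_informative", "best_snv": None,
                 "beta": np.nan, "r2": np.nan, "p": np.nan, "q": np.nan}
            )
            continue
        best = grp.loc[grp["r2"].idxmax()]
        summaries.append(
            {
                "corsiv_id": cid,
                "call": "positive" if grp["positive"].any() else "negative",
                "best_snv": best["snv_id"],
                "beta": best["beta"],
                "r2": best["r2"],
                "p": best["p"],
                "q": best["q"],
            }
        )
    return tests, pd.DataFrame(summaries)


# ---------------------------------------------------------------------------
# pairwise donor concordance


def pairwise_geno_meth(
    corsivs: pd.DataFrame,
    pooled_means: np.ndarray,
    genotypes: pd.DataFrame,
    individuals: list[str],
    window: int = 10_000,
) -> pd.DataFrame:
    """Donor-pair concordance of methylation and local genotype differences.

    For each unordered donor pair, across regions: x = |difference of mean
    additive genotype over SNVs within ``window`` of the region|, y =
    |difference of pooled region methylation|; the R^2 of the x-y OLS fit
    summarizes how much interindividual methylation variation tracks local
    genetic variation.  Returns one row per pair plus the R^2.
    """
    G = genotype_matrix(genotypes, individuals)
    gpos = genotypes["pos"].to_numpy()
    gchrom = genotypes["chrom"].to_numpy()
    n_ind = len(individuals)
    mean_g = np.full((len(corsivs), n_ind), np.nan)
    for k, reg in corsivs.reset_index(drop=True).iterrows():
        sel = (
            (gchrom == reg["chrom"])
            & (gpos >= reg["start"] - window)
            & (gpos < reg["end"] + window)
        )
        if sel.any():
            mean_g[k] = np.nanmean(G[sel], axis=0)
    rows = []
    for i, j in itertools.combinations(range(n_ind), 2):
        x = np.abs(mean_g[:, i] - mean_g[:, j])
        y = np.abs(pooled_means[:, i] - pooled_means[:, j])
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() < 3:
            log.info("pair (%s, %s): fewer than 3 informative regions, skipped",
                     individuals[i], individuals[j])
            continue
        if x[ok].std() == 0 or y[ok].std() == 0:
            r2 = 0.0
        else:
            r2 = stats.linregress(x[ok], y[ok]).rvalue ** 2
        rows.append(
            {"ind_a": individuals[i], "ind_b": individuals[j],
             "n_regions": int(ok.sum()), "r2": r2}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CNV / read-depth check


def depth_meth_correlation(region, bm: BinMatrix) -> tuple[float, float]:
    """Spearman correlation of per-individual mean region read depth vs
    pooled region methylation; (NaN, NaN) when depth is constant."""
    one = pd.DataFrame([{"bin_ids": np.asarray(region["bin_ids"])}])
    _, pooled, depth_mean = region_stats(bm, one)
    d = depth_mean[0]
    m = pooled[0]
    ok = ~np.isnan(d) & ~np.isnan(m)
    if ok.sum() < 4:
        raise ValueError("need at least 4 individuals with depth and methylation")
    if np.all(d[ok] == d[ok][0]):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(d[ok], m[ok])
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# methylation decay vs LD decay


@dataclass
class DecayProfile:
    corsiv_id: str
    profile: pd.DataFrame  # distance_bin, meth_r2, ld_r2
    spearman_rho: float
    p: float
    note: str = ""


def decay_comparison(
    region,
    bm: BinMatrix,
    genotypes: pd.DataFrame,
    window: int = 20_000,
    dist_bin: int = 1_000,
) -> DecayProfile:
    """Compare methylation-correlation decay with LD decay in the flanks.

    Methylation side: squared Pearson correlation (across individuals, on
    pooled bin methylation) for every (inside-bin, flanking-bin) pair within
    ``window`` bp of the region boundary.  LD side: composite r^2 for every
    (inside-SNV, flanking-SNV) pair in the same window.  Both are averaged
    within shared ``dist_bin``-bp distance bins (distance measured from the
    region boundary; distances of exactly ``window`` are included) and
    compared by Spearman correlation.
    """
    bin_ids = np.asarray(region["bin_ids"])
    chrom, start, end = region["chrom"], region["start"], region["end"]
    n_dist = window // dist_bin

    def dist_idx(d):
        return np.minimum(d // dist_bin, n_dist - 1).astype(int)

    pooled = bm.pooled_meth
    starts = bm.bins["start"].to_numpy()
    ends = bm.bins["end"].to_numpy()
    on_chrom = bm.bins["chrom"].to_numpy() == chrom
    left = on_chrom & (ends <= start) & (start - ends <= window)
    right = on_chrom & (starts >= end) & (starts - end <= window)
    flank = np.flatnonzero(left | right)
    flank = flank[~np.isin(flank, bin_ids)]
    flank_dist = np.where(
        ends[flank] <= start, start - ends[flank], starts[flank] - end
    )
    ok_rows = ~np.isnan(pooled[flank]).any(axis=1)
    flank, flank_dist = flank[ok_rows], flank_dist[ok_rows]
    if len(flank) < 3:
        return DecayProfile(region.get("region_id", ""), pd.DataFrame(),
                            float("nan"), float("nan"),
                            "fewer than 3 informative flanking bins")

    meth_sum = np.zeros(n_dist)
    meth_n = np.zeros(n_dist)
    for b in bin_ids:
        if np.isnan(pooled[b]).any():
            continue
        r = _rowwise_pearson(
            np.broadcast_to(pooled[b], (len(flank), pooled.shape[1])), pooled[flank]
        )
        d = dist_idx(flank_dist)
        good = ~np.isnan(r)
        np.add.at(meth_sum, d[good], r[good] ** 2)
        np.add.at(meth_n, d[good], 1)

    gsel = genotypes["chrom"].to_numpy() == chrom
    gpos = genotypes["pos"].to_numpy()
    inside = gsel & (gpos >= start) & (gpos < end)
    fl_left = gsel & (gpos < start) & (start - gpos <= window)
    fl_right = gsel & (gpos >= end) & (gpos - end + 1 <= window)
    fl = np.flatnonzero(fl_left | fl_right)
    ins = np.flatnonzero(inside)
    ind_cols = [c for c in genotypes.columns if c not in ("snv_id", "chrom", "pos", "block")]
    if len(fl) < 3 or len(ins) == 0:
        return DecayProfile(region.get("region_id", ""), pd.DataFrame(),
                            float("nan"), float("nan"),
                            "fewer than 3 flanking SNVs (or none inside)")
    Gm = genotypes[ind_cols].to_numpy(dtype=float)
    ld_sum = np.zeros(n_dist)
    ld_n = np.zeros(n_dist)
    fdist = np.where(gpos[fl] < start, start - gpos[fl], gpos[fl] - end + 1)
    for s in ins:
        for f, dd in zip(fl, dist_idx(fdist)):
            r2 = ld_r2(Gm[s], Gm[f])
            if not np.isnan(r2):
                ld_sum[dd] += r2
                ld_n[dd] += 1

    with np.errstate(invalid="ignore"):
        meth_prof = np.where(meth_n > 0, meth_sum / np.maximum(meth_n, 1), np.nan)
        ld_prof = np.where(ld_n > 0, ld_sum / np.maximum(ld_n, 1), np.nan)
    shared = ~np.isnan(meth_prof) & ~np.isnan(ld_prof)
    profile = pd.DataFrame(
        {
            "distance_bin": np.arange(n_dist) * dist_bin,
            "meth_r2": meth_prof,
            "ld_r2": ld_prof,
        }
    )
    if shared.sum() < 3:
        return DecayProfile(region.get("region_id", ""), profile,
                            float("nan"), float("nan"),
                            "fewer than 3 shared distance bins")
    rho, p = stats.spearmanr(meth_prof[shared], ld_prof[shared])
    return DecayProfile(region.get("region_id", ""), profile, float(rho), float(p))
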