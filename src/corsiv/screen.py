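"""The CoRSIV screen.

Two-stage design: (1) pool each individual's reads across tissues and build
*correlated regions* of adjacent 100-bp bins step-wise — a candidate bin
joins the open region when the Pearson correlation between its
per-individual pooled methylation profile and the running region-mean
profile is >= ``r_min`` (0.71, i.e. R^2 >= 0.5); (2) for every region with
>= 2 bins, compute the inter-tissue correlation (ITC) of region-average
methylation across individuals for every tissue pair, and call the region
systemic when the *minimum* ITC over pairs is >= the threshold.  Called
regions are then filtered to those with >= 5 CpGs and an interindividual
methylation range (IIR, max - min of pooled region methylation) of >= 20
percentage points.

The module exposes both the individual operations and a statsmodels-style
model object, :class:`CorsivScreen`, whose :meth:`~CorsivScreen.fit` returns
a :class:`CorsivScreenResults` carrying the candidate and called region
tables, the permutation null, and a ``summary()``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .binmatrix import BinMatrix

log = logging.getLogger(__name__)


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation; NaN if either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0 or sy == 0:
        return float("nan")
    return float((xc * yc).sum() / (sx * sy))


def _rowwise_pearson(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of X with the matching row of Y."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = (Xc * Yc).sum(axis=1)
    den = np.sqrt((Xc * Xc).sum(axis=1) * (Yc * Yc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return r


def build_correlated_regions(
    bm: BinMatrix,
    r_min: float = 0.71,
    max_gap_bp: int = 0,
    min_bins: int = 2,
    informative: np.ndarray | None = None,
) -> pd.DataFrame:
    """Greedy left-to-right construction of correlated regions per chromosome.

    A region opens at the first unused informative bin and extends to the
    next informative bin iff the genomic gap between consecutive bins is
    <= ``max_gap_bp`` and the Pearson R between the candidate bin's pooled
    per-individual profile and the current region's mean profile is
    >= ``r_min``; it closes on the first failure.  Regions with fewer than
    ``min_bins`` bins are dropped; emitted regions are disjoint.

    Returns a DataFrame with columns ``region_id, chrom, start, end, n_bins,
    n_cpgs, bin_ids`` (``bin_ids`` holds integer indices into ``bm.bins``).
    """
    if informative is None:
        informative = bm.informative_mask()
    pooled = bm.pooled_meth
    starts = bm.bins["start"].to_numpy()
    ends = bm.bins["end"].to_numpy()
    ncpg = bm.bins["n_cpgs"].to_numpy()
    chrom_arr = bm.bins["chrom"].to_numpy()

    regions = []
    usable = informative & ~np.isnan(pooled).any(axis=1)
    n_dropped = int(informative.sum() - usable.sum())
    if n_dropped:
        log.info("dropped %d informative bins with missing pooled values", n_dropped)

    for chrom in pd.unique(chrom_arr):
        idx = np.flatnonzero((chrom_arr == chrom) & usable)
        if len(idx) == 0:
            continue
        cur: list[int] = []
        cur_sum = None
        for b in idx:
            if cur:
                gap = starts[b] - ends[cur[-1]]
                if gap <= max_gap_bp:
                    r = pearson_r(pooled[b], cur_sum / len(cur))
                    if not np.isnan(r) and r >= r_min:
                        cur.append(b)
                        cur_sum = cur_sum + pooled[b]
                        continue
                if len(cur) >= min_bins:
                    regions.append(cur)
                cur = []
            cur = [b]
            cur_sum = pooled[b].copy()
        if len(cur) >= min_bins:
            regions.append(cur)

    rows = []
    for k, bin_ids in enumerate(regions):
        bin_ids = np.asarray(bin_ids)
        chrom = chrom_arr[bin_ids[0]]
        rows.append(
            {
                "region_id": f"{chrom}_{k}",
                "chrom": chrom,
                "start": int(starts[bin_ids[0]]),
                "end": int(ends[bin_ids[-1]]),
                "n_bins": len(bin_ids),
                "n_cpgs": int(ncpg[bin_ids].sum()),
                "bin_ids": bin_ids,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["region_id", "chrom", "start", "end", "n_bins", "n_cpgs", "bin_ids"],
    )


# ---------------------------------------------------------------------------
# region-level statistics


def region_stats(bm: BinMatrix, regions: pd.DataFrame):
    """Read-weighted region means for a region table.

    Returns ``(tissue_means, pooled_means, pooled_depth_mean)``:

    * ``tissue_means`` — (n_regions, n_individuals, n_tissues) percent
      methylation (read-weighted over member bins);
    * ``pooled_means`` — (n_regions, n_individuals) percent methylation after
      pooling the individual's reads across tissues;
    * ``pooled_depth_mean`` — (n_regions, n_individuals) mean per-bin pooled
      read depth.
    """
    inds = bm.individuals
    tissues = bm.tissues
    n_r = len(regions)
    cat = np.concatenate([np.asarray(b) for b in regions["bin_ids"]]) if n_r else np.empty(0, int)
    seg = np.concatenate([[0], np.cumsum([len(b) for b in regions["bin_ids"]])])[:-1]
    nb = np.array([len(b) for b in regions["bin_ids"]])

    mc = np.add.reduceat(bm.meth_counts[cat], seg, axis=0) if n_r else np.empty((0, len(bm.samples)))
    tc = np.add.reduceat(bm.total_counts[cat], seg, axis=0) if n_r else np.empty((0, len(bm.samples)))

    col_ind = np.array([inds.index(i) for i, _ in bm.samples])
    col_tis = np.array([tissues.index(t) for _, t in bm.samples])
    tm_m = np.zeros((n_r, len(inds), len(tissues)))
    tm_t = np.zeros_like(tm_m)
    for j in range(len(bm.samples)):
        tm_m[:, col_ind[j], col_tis[j]] += mc[:, j]
        tm_t[:, col_ind[j], col_tis[j]] += tc[:, j]
    with np.errstate(invalid="ignore", divide="ignore"):
        tissue_means = np.where(tm_t > 0, 100.0 * tm_m / tm_t, np.nan)
        pm = tm_m.sum(axis=2)
        pt = tm_t.sum(axis=2)
        pooled_means = np.where(pt > 0, 100.0 * pm / pt, np.nan)
    pooled_depth_mean = pt / nb[:, None] if n_r else pt
    return tissue_means, pooled_means, pooled_depth_mean


def itc_from_tissue_means(tissue_means: np.ndarray) -> tuple[np.ndarray, list]:
    """Per-region ITC matrix (n_regions, n_pairs) and the tissue-pair list.

    ITC is the Pearson correlation across individuals of two tissues'
    region-average methylation; rows with a constant or missing tissue
    profile yield NaN for the affected pair.
    """
    n_t = tissue_means.shape[2]
    pairs = list(itertools.combinations(range(n_t), 2))
    out = np.empty((tissue_means.shape[0], len(pairs)))
    for k, (a, b) in enumerate(pairs):
        out[:, k] = _rowwise_pearson(tissue_means[:, :, a], tissue_means[:, :, b])
    return out, pairs


def inter_tissue_correlation(region, bm: BinMatrix):
    """ITC of one region: dict of per-tissue-pair Pearson R plus the minimum.

    ``region`` is a row of the table from :func:`build_correlated_regions`
    (anything with a ``bin_ids`` entry).
    """
    one = pd.DataFrame([{"bin_ids": np.asarray(region["bin_ids"])}])
    tm, _, _ = region_stats(bm, one)
    itcs, pairs = itc_from_tissue_means(tm)
    tissues = bm.tissues
    named = {
        (tissues[a], tissues[b]): float(itcs[0, k]) for k, (a, b) in enumerate(pairs)
    }
    vals = itcs[0]
    min_itc = float(np.min(vals)) if not np.isnan(vals).any() else float("nan")
    return named, min_itc


def itc_screen(regions: pd.DataFrame, itc_min: float = 0.71) -> pd.DataFrame:
    """Keep regions whose minimum inter-tissue correlation passes the
    threshold (inclusive: min ITC exactly at the threshold is systemic);
    regions with undefined ITC are excluded."""
    keep = (regions["min_itc"] >= itc_min).fillna(False)
    return regions.loc[keep].reset_index(drop=True)


def corsiv_filters(
    candidates: pd.DataFrame, min_cpgs: int = 5, min_iir: float = 20.0
) -> pd.DataFrame:
    """Keep candidates with >= ``min_cpgs`` CpGs and IIR >= ``min_iir`` pp
    (thresholds inclusive)."""
    keep = (candidates["n_cpgs"] >= min_cpgs) & (candidates["iir"] >= min_iir)
    return candidates.loc[keep].reset_index(drop=True)


def cluster_samples(bm: BinMatrix, bin_subset, k: int | None = None):
    """Average-linkage hierarchical clustering of samples on 1 - Pearson R.

    Bins with a missing value in any sample are dropped.  Returns
    ``(linkage, labels)``; ``labels`` is the flat ``k``-cluster cut (or None
    when ``k`` is not given).
    """
    if len(bm.samples) < 3:
        raise ValueError("need at least 3 samples to cluster")
    bin_subset = np.asarray(bin_subset)
    if bin_subset.dtype == bool:
        bin_subset = np.flatnonzero(bin_subset)
    if len(bin_subset) == 0:
        raise ValueError("empty bin subset")
    M = bm.meth[bin_subset]
    M = M[~np.isnan(M).any(axis=1)]
    if M.shape[0] < 2:
        raise ValueError("fewer than 2 usable bins after dropping missing values")
    C = np.corrcoef(M.T)
    D = np.clip(1.0 - C, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    Z = sch.linkage(squareform(D, checks=False), method="average")
    labels = sch.fcluster(Z, t=k, criterion="maxclust") if k else None
    return Z, labels


# ---------------------------------------------------------------------------
# model object


@dataclass
class CorsivScreen:
    """Model object: the CoRSIV screen over a :class:`BinMatrix`.

    Parameters hold the screen's thresholds: ``r_min`` for step-wise region
    building, ``itc_min`` for the systemic call (both 0.71, R^2 >= 0.5),
    ``min_cpgs``/``min_iir`` for the robustness filters, and the
    informative-bin criteria.
    """

    bm: BinMatrix
    r_min: float = 0.71
    itc_min: float = 0.71
    min_cpgs: int = 5
    min_iir: float = 20.0
    max_gap_bp: int = 0
    min_bins: int = 2
    min_depth: int = 10
    min_fraction_samples: float = 1.0

    def __post_init__(self):
        n_t = len(self.bm.tissues)
        if n_t < 2:
            raise ValueError("screen requires at least 2 tissues")
        if n_t < 3:
            log.warning("only %d tissues: systemic calls are weakly constrained", n_t)

    def fit(
        self,
        n_perm: int = 0,
        blocks_per_perm: int = 1000,
        seed: int | None = None,
    ) -> "CorsivScreenResults":
        from .permutation import permute_null, region_p_value

        informative = self.bm.informative_mask(
            min_depth=self.min_depth, min_fraction_samples=self.min_fraction_samples
        )
        regions = build_correlated_regions(
            self.bm,
            r_min=self.r_min,
            max_gap_bp=self.max_gap_bp,
            min_bins=self.min_bins,
            informative=informative,
        )
        tm, pooled_means, _ = region_stats(self.bm, regions)
        itcs, pairs = itc_from_tissue_means(tm)
        tissues = self.bm.tissues
        regions = regions.copy()
        for k, (a, b) in enumerate(pairs):
            regions[f"itc_{tissues[a]}_{tissues[b]}"] = itcs[:, k]
        with np.errstate(invalid="ignore"):
            regions["min_itc"] = np.where(
                np.isnan(itcs).any(axis=1), np.nan, itcs.min(axis=1, initial=np.inf)
            )
            regions["iir"] = np.nanmax(pooled_means, axis=1) - np.nanmin(
                pooled_means, axis=1
            ) if len(regions) else np.empty(0)

        n_degenerate = int(np.isnan(regions["min_itc"]).sum())
        if n_degenerate:
            log.info("excluded %d regions with undefined ITC", n_degenerate)
        candidates = itc_screen(regions, self.itc_min)
        corsivs = corsiv_filters(candidates, self.min_cpgs, self.min_iir)

        null = None
        if n_perm > 0:
            null = permute_null(
                tm, n_perm=n_perm, blocks_per_perm=blocks_per_perm, seed=seed
            )
            corsivs = corsivs.copy()
            corsivs["p_perm"] = region_p_value(
                corsivs["min_itc"].to_numpy(), null
            )
        return CorsivScreenResults(
            model=self,
            informative=informative,
            regions=regions,
            candidates=candidates,
            corsivs=corsivs,
            pooled_means=pooled_means,
            tissue_means=tm,
            null=null,
        )


@dataclass
class CorsivScreenResults:
    """Results of :meth:`CorsivScreen.fit`.

    ``regions`` is the full correlated-region table with per-pair ITCs,
    ``min_itc`` and ``iir``; ``candidates`` the subset passing the ITC
    screen; ``corsivs`` the final calls after the CpG-count and IIR filters
    (with ``p_perm`` when a permutation null was run).
    """

    model: CorsivScreen
    informative: np.ndarray
    regions: pd.DataFrame
    candidates: pd.DataFrame
    corsivs: pd.DataFrame
    pooled_means: np.ndarray
    tissue_means: np.ndarray
    null: object | None = None

    def summary(self) -> str:
        m = self.model
        lines = [
            "CoRSIV screen summary",
            "=====================",
            f"samples:            {len(m.bm.samples)} "
            f"({len(m.bm.individuals)} individuals x {len(m.bm.tissues)} tissues)",
            f"bins:               {m.bm.n_bins} ({int(self.informative.sum())} informative)",
            f"correlated regions: {len(self.regions)} (R >= {m.r_min}, "
            f"min {m.min_bins} bins)",
            f"ITC screen:         {len(self.candidates)} regions with min ITC >= {m.itc_min}",
            f"CoRSIVs:            {len(self.corsivs)} "
            f"(>= {m.min_cpgs} CpGs, IIR >= {m.min_iir} pp)",
        ]
        if self.null is not None:
            lines.append(
                f"permutation null:   chance rate at ITC {m.itc_min} = "
                f"{100 * self.null.chance_rate(m.itc_min):.3g}% "
                f"({self.null.n_perm} permutations)"
            )
        if len(self.corsivs):
            lines.append(
                f"median CoRSIV:      {int(self.corsivs['n_bins'].median())} bins, "
                f"{int(self.corsivs['n_cpgs'].median())} CpGs, "
                f"IIR {self.corsivs['iir'].median():.1f} pp, "
                f"min ITC {self.corsivs['min_itc'].median():.3f}"
            )
        return "\n".join(lines)

    def corsiv_sample_matrix(self, region_id: str) -> pd.DataFrame:
        """Individual x tissue region-mean methylation for one called region."""
        for df in (self.corsivs, self.candidates, self.regions):
            hit = df.index[df["region_id"] == region_id]
            if len(hit):
                break
        else:
            raise KeyError(region_id)
        k = self.regions.index[self.regions["region_id"] == region_id][0]
        bm = self.model.bm
        return pd.DataFrame(
            self.tissue_means[k], index=bm.individuals, columns=bm.tissues
        )

    def to_bed(self, path) -> None:
        """Write the called CoRSIVs as BED (score = floor(100 * min ITC))."""
        from .io import write_bed

        df = self.corsivs.copy()
        df["name"] = df["region_id"]
        df["score"] = np.floor(100 * df["min_itc"]).astype(int)
        write_bed(df, path)

    def to_table(self, path) -> None:
        df = self.corsivs.drop(columns=["bin_ids"])
        df.to_csv(path, sep="\t", index=False)

    def plot_iir_vs_cpgs(self, ax=None):
        """Scatter of interindividual range vs CpG count for all candidates,
        with the filter thresholds marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.candidates["n_cpgs"], self.candidates["iir"], s=6, alpha=0.5)
        ax.axhline(self.model.min_iir, color="r", lw=0.8)
        ax.axvline(self.model.min_cpgs, color="r", lw=0.8)
        ax.set_xlabel("CpGs per region")
        ax.set_ylabel("interindividual range (pp)")
        return ax
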