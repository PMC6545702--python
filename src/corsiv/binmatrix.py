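"""Fixed-width bin representation of multi-sample CpG methylation.

The screen does not operate on individual CpGs but on 100-bp genomic bins.
Bin methylation is read-weighted: the percent is computed from the summed
methylated and total read counts of all CpGs falling in the bin, so that
pooling reads across tissues and binning commute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import SEX_CHROMS


@dataclass
class BinMatrix:
    """Per-(bin, sample) methylation counts with (individual, tissue) labels.

    Attributes
    ----------
    bins : DataFrame with columns ``chrom, start, end, n_cpgs`` (``n_cpgs`` =
        distinct covered CpG positions in the bin across all samples), sorted
        by (chrom, start), non-overlapping, fixed width.
    samples : list of (individual, tissue) tuples, one per column.
    meth_counts, total_counts : int arrays of shape (n_bins, n_samples).
    """

    bins: pd.DataFrame
    samples: list[tuple[str, str]]
    meth_counts: np.ndarray
    total_counts: np.ndarray
    bin_size: int = 100
    _pooled: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.samples = [tuple(s) for s in self.samples]
        if self.meth_counts.shape != (len(self.bins), len(self.samples)):
            raise ValueError("count matrix shape does not match bins x samples")
        if np.any(self.meth_counts > self.total_counts):
            raise ValueError("methylated counts exceed total counts")

    # -- sample axis -------------------------------------------------------
    @property
    def individuals(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind, _ in self.samples:
            seen.setdefault(ind)
        return list(seen)

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, tis in self.samples:
            seen.setdefault(tis)
        return list(seen)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    # -- methylation -------------------------------------------------------
    @property
    def meth(self) -> np.ndarray:
        """Percent methylation (n_bins, n_samples); NaN where depth is 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.total_counts > 0,
                100.0 * self.meth_counts / self.total_counts,
                np.nan,
            )

    @property
    def depth(self) -> np.ndarray:
        return self.total_counts

    # -- pooling across tissues -------------------------------------------
    def pool_by_individual(self) -> tuple[np.ndarray, np.ndarray]:
        """Read-pooled (meth_counts, total_counts) per (bin, individual).

        Equivalent to combining all of an individual's reads before binning;
        tissues with zero depth contribute nothing.
        """
        if self._pooled is None:
            inds = self.individuals
            idx = {ind: k for k, ind in enumerate(inds)}
            pm = np.zeros((self.n_bins, len(inds)), dtype=np.int64)
            pt = np.zeros_like(pm)
            for j, (ind, _) in enumerate(self.samples):
                k = idx[ind]
                pm[:, k] += self.meth_counts[:, j]
                pt[:, k] += self.total_counts[:, j]
            self._pooled = (pm, pt)
        return self._pooled

    @property
    def pooled_meth(self) -> np.ndarray:
        """Percent pooled methylation (n_bins, n_individuals); NaN if no reads."""
        pm, pt = self.pool_by_individual()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(pt > 0, 100.0 * pm / pt, np.nan)

    @property
    def pooled_depth(self) -> np.ndarray:
        return self.pool_by_individual()[1]

    # -- masks & subsets ---------------------------------------------------
    def informative_mask(
        self,
        min_cpgs: int = 1,
        min_depth: int = 10,
        min_fraction_samples: float = 1.0,
    ) -> np.ndarray:
        """Bins usable by the screen.

        A bin is informative iff it contains at least ``min_cpgs`` covered
        CpG sites and its pooled read depth is >= ``min_depth`` in at least
        ``min_fraction_samples`` of individuals.
        """
        pt = self.pool_by_individual()[1]
        frac_ok = (pt >= min_depth).mean(axis=1)
        return (self.bins["n_cpgs"].to_numpy() >= min_cpgs) & (
            frac_ok >= min_fraction_samples
        )

    def subset(self, bin_index) -> "BinMatrix":
        bin_index = np.asarray(bin_index)
        return BinMatrix(
            bins=self.bins.iloc[bin_index].reset_index(drop=True),
            samples=list(self.samples),
            meth_counts=self.meth_counts[bin_index],
            total_counts=self.total_counts[bin_index],
            bin_size=self.bin_size,
        )

    def sample_columns(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_tuples(self.samples, names=["individual", "tissue"])


def bin_methylation(
    tables: Mapping[tuple[str, str], pd.DataFrame],
    bin_size: int = 100,
    exclude_sex_chroms: bool = True,
) -> BinMatrix:
    """Reduce per-CpG call tables to the fixed-width bin representation.

    Parameters
    ----------
    tables : mapping (individual, tissue) -> DataFrame with columns
        ``chrom, pos, n_meth, n_total`` (as returned by
        :func:`corsiv.io.read_cpg_table`).
    bin_size : bin width in bp; bin start = floor(pos / bin_size) * bin_size.

    Bin methylation is 100 x sum(n_meth) / sum(n_total) over the bin's CpGs
    (read-weighted); bins with no covered CpG in a sample have zero depth and
    undefined methylation there.  Sex chromosomes are dropped by default.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    samples = list(tables)
    pieces = []
    for j, s in enumerate(samples):
        df = tables[s]
        if exclude_sex_chroms:
            df = df[~df["chrom"].isin(SEX_CHROMS)]
        df = df[df["n_total"] > 0]
        pieces.append(
            pd.DataFrame(
                {
                    "chrom": df["chrom"].to_numpy(),
                    "bin": (df["pos"].to_numpy() // bin_size) * bin_size,
                    "pos": df["pos"].to_numpy(),
                    "n_meth": df["n_meth"].to_numpy(),
                    "n_total": df["n_total"].to_numpy(),
                    "sample": np.full(len(df), j, dtype=np.int32),
                }
            )
        )
    big = pd.concat(pieces, ignore_index=True)
    if len(big) == 0:
        raise ValueError("no covered CpGs in any sample")

    counts = (
        big.groupby(["chrom", "bin", "sample"], sort=True, observed=True)[
            ["n_meth", "n_total"]
        ]
        .sum()
        .reset_index()
    )
    cpgs = (
        big[["chrom", "bin", "pos"]]
        .drop_duplicates()
        .groupby(["chrom", "bin"], sort=True)
        .size()
    )

    bins = cpgs.index.to_frame(index=False).rename(columns={"bin": "start"})
    bins["end"] = bins["start"] + bin_size
    bins["n_cpgs"] = cpgs.to_numpy()
    bins = bins[["chrom", "start", "end", "n_cpgs"]]

    key = pd.MultiIndex.from_frame(bins[["chrom", "start"]])
    row = pd.Series(np.arange(len(bins)), index=key)
    ridx = row.loc[
        pd.MultiIndex.from_frame(counts[["chrom", "bin"]])
    ].to_numpy()

    mc = np.zeros((len(bins), len(samples)), dtype=np.int64)
    tc = np.zeros_like(mc)
    cj = counts["sample"].to_numpy()
    mc[ridx, cj] = counts["n_meth"].to_numpy()
    tc[ridx, cj] = counts["n_total"].to_numpy()

    return BinMatrix(
        bins=bins, samples=samples, meth_counts=mc, total_counts=tc, bin_size=bin_size
    )
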