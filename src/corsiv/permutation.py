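"""Empirical null for the inter-tissue-correlation screen.

Scrambling subject identity independently within each tissue destroys the
individual linkage that systemic variation creates while preserving each
tissue's marginal distribution.  Per permutation, a fixed number of regions
is sampled with replacement and the minimum ITC recomputed; the pooled draws
form the null distribution of the screen statistic, from which both the
chance calling rate at a threshold and per-region p-values are obtained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .screen import itc_from_tissue_means


@dataclass
class NullDistribution:
    """Sampled null minimum-ITC values.

    ``null_min_itc`` holds ``n_perm * blocks_per_perm`` draws minus the
    degenerate (undefined-correlation) draws, whose count is recorded in
    ``n_excluded``.
    """

    null_min_itc: np.ndarray
    n_perm: int
    blocks_per_perm: int
    n_excluded: int
    seed: int | None

    def chance_rate(self, tau: float) -> float:
        """Fraction of null draws with minimum ITC >= ``tau``."""
        return float(np.mean(self.null_min_itc >= tau))

    def __post_init__(self):
        self.null_min_itc = np.sort(np.asarray(self.null_min_itc, dtype=float))


def permute_null(
    tissue_means: np.ndarray,
    n_perm: int,
    blocks_per_perm: int = 1000,
    seed: int | None = None,
    rng=None,
) -> NullDistribution:
    """Permutation null of the minimum inter-tissue correlation.

    Parameters
    ----------
    tissue_means : (n_regions, n_individuals, n_tissues) region-average
        methylation (as produced by :func:`corsiv.screen.region_stats`).
    n_perm : number of permutations; in each, subject labels are shuffled
        independently within every tissue and ``blocks_per_perm`` regions are
        sampled with replacement.
    seed : mandatory unless ``rng`` is supplied; the identity permutation
        (no tissue shuffled) is redrawn, never counted as a null draw.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tissue_means.shape[0] < 2:
        raise ValueError("need at least 2 regions to permute")
    if rng is None:
        if seed is None:
            raise ValueError("seed is mandatory")
        rng = np.random.default_rng(seed)

    n_regions, n_ind, n_tis = tissue_means.shape
    draws = []
    n_excluded = 0
    for _ in range(n_perm):
        while True:
            perms = [rng.permutation(n_ind) for _ in range(n_tis)]
            if any(not np.array_equal(p, np.arange(n_ind)) for p in perms):
                break
        block_idx = rng.integers(0, n_regions, size=blocks_per_perm)
        M = np.empty((blocks_per_perm, n_ind, n_tis))
        for t in range(n_tis):
            M[:, :, t] = tissue_means[block_idx][:, perms[t], t]
        itcs, _ = itc_from_tissue_means(M)
        with np.errstate(invalid="ignore"):
            bad = np.isnan(itcs).any(axis=1)
            mins = itcs.min(axis=1)
        n_excluded += int(bad.sum())
        draws.append(mins[~bad])
    null = np.concatenate(draws) if draws else np.empty(0)
    if null.size == 0:
        raise ValueError("all permutation draws were degenerate (undefined ITC)")
    return NullDistribution(
        null_min_itc=null,
        n_perm=n_perm,
        blocks_per_perm=blocks_per_perm,
        n_excluded=n_excluded,
        seed=seed,
    )


def region_p_value(observed_min_itc, null: NullDistribution):
    """Add-one permutation p-value: (1 + #{null >= obs}) / (1 + N).

    Accepts a scalar or an array of observed minimum ITCs.
    """
    obs = np.asarray(observed_min_itc, dtype=float)
    sorted_null = null.null_min_itc
    n = sorted_null.size
    n_ge = n - np.searchsorted(sorted_null, obs, side="left")
    p = (1.0 + n_ge) / (1.0 + n)
    if np.ndim(observed_min_itc) == 0:
        return float(p)
    return p
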