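"""Genomic-context statistics: matched controls, enrichments, clustering,
superCoRSIVs, TAD containment and probe mapping.

All interval arithmetic is 0-based half-open; a region "overlaps" a feature
set iff it intersects at least one bp of it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

log = logging.getLogger(__name__)


def _trees(features: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in features.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(grp["start"], grp["end"]) if e > s
        )
    return trees


def overlap_flags(regions: pd.DataFrame, features: pd.DataFrame) -> np.ndarray:
    """Boolean per region: intersects >= 1 bp of the feature set."""
    trees = _trees(features)
    out = np.zeros(len(regions), dtype=bool)
    for k, (chrom, s, e) in enumerate(
        zip(regions["chrom"], regions["start"], regions["end"])
    ):
        t = trees.get(chrom)
        if t is not None and t.overlaps(int(s), int(e)):
            out[k] = True
    return out


@dataclass
class EnrichmentResult:
    feature: str
    table: np.ndarray  # 2x2: rows (set A, set B), cols (overlap, no overlap)
    odds_ratio: float
    test: str
    p: float


def _odds_ratio(table: np.ndarray) -> float:
    a, b = table[0]
    c, d = table[1]
    if min(a, b, c, d) == 0:  # Haldane correction keeps the OR finite
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    return float((a * d) / (b * c))


def enrichment_from_flags(
    flags_a: np.ndarray,
    flags_b: np.ndarray,
    test: str = "chi2",
    feature: str = "",
) -> EnrichmentResult:
    """2x2 enrichment of overlap status between two region sets.

    ``test``: ``chi2`` (Yates continuity correction), ``fisher``, or
    ``auto`` (Fisher when any expected cell < 5).
    """
    table = np.array(
        [
            [int(flags_a.sum()), int((~flags_a).sum())],
            [int(flags_b.sum()), int((~flags_b).sum())],
        ]
    )
    if table[0].sum() == 0 or table[1].sum() == 0:
        raise ValueError("empty region set")
    if test == "auto":
        tot = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / tot
        test = "fisher" if (expected < 5).any() else "chi2"
    if test == "chi2":
        col = table.sum(axis=0)
        if (col == 0).any():
            p = 1.0  # degenerate: all regions share one overlap status
        else:
            _, p, _, _ = stats.chi2_contingency(table, correction=True)
    elif test == "fisher":
        _, p = stats.fisher_exact(table)
    else:
        raise ValueError(f"unknown test {test!r}")
    return EnrichmentResult(
        feature=feature,
        table=table,
        odds_ratio=_odds_ratio(table),
        test=test,
        p=float(p),
    )


def feature_enrichment(
    regions_a: pd.DataFrame,
    regions_b: pd.DataFrame,
    features: pd.DataFrame,
    test: str = "chi2",
    feature_name: str = "",
) -> EnrichmentResult:
    """Enrichment of feature overlap in region set A relative to set B."""
    if len(features) == 0:
        raise ValueError("empty feature set")
    if len(regions_a) == 0 or len(regions_b) == 0:
        raise ValueError("empty region set")
    fa = overlap_flags(regions_a, features)
    fb = overlap_flags(regions_b, features)
    return enrichment_from_flags(fa, fb, test=test, feature=feature_name)


# ---------------------------------------------------------------------------
# matched controls


def sample_matched_controls(
    corsivs: pd.DataFrame,
    bins: pd.DataFrame,
    informative: np.ndarray,
    bin_size: int = 100,
    tolerance: float = 0.1,
    seed: int | None = None,
    max_tries: int = 2000,
):
    """Rejection-sample one control region per CoRSIV, matched on chromosome,
    length and CpG content (within ``tolerance`` of the target count).

    Controls are placed on the bin grid over fully informative territory and
    are disjoint from all CoRSIVs and from each other.  Returns
    ``(controls, unmatched_ids)``.
    """
    if seed is None:
        raise ValueError("seed is mandatory")
    rng = np.random.default_rng(seed)
    chrom_arr = bins["chrom"].to_numpy()
    ncpg = bins["n_cpgs"].to_numpy()
    chrom_rows = {c: np.flatnonzero(chrom_arr == c) for c in pd.unique(chrom_arr)}
    occupied = np.zeros(len(bins), dtype=bool)
    start_arr = bins["start"].to_numpy()
    for _, reg in corsivs.iterrows():
        rows = chrom_rows.get(reg["chrom"], np.empty(0, int))
        inside = rows[
            (start_arr[rows] >= reg["start"]) & (start_arr[rows] < reg["end"])
        ]
        occupied[inside] = True

    controls = []
    unmatched = []
    for _, reg in corsivs.iterrows():
        rows = chrom_rows.get(reg["chrom"], np.empty(0, int))
        nb = int(round((reg["end"] - reg["start"]) / bin_size))
        target = reg["n_cpgs"]
        placed = False
        for _ in range(max_tries):
            if len(rows) <= nb:
                break
            s = int(rng.integers(0, len(rows) - nb))
            win = rows[s : s + nb]
            # window must be contiguous bins on the grid
            if start_arr[win[-1]] - start_arr[win[0]] != (nb - 1) * bin_size:
                continue
            if not informative[win].all() or occupied[win].any():
                continue
            c = int(ncpg[win].sum())
            if abs(c - target) > tolerance * target:
                continue
            occupied[win] = True
            controls.append(
                {
                    "region_id": f"ctrl_{reg['region_id']}",
                    "corsiv_id": reg["region_id"],
                    "chrom": reg["chrom"],
                    "start": int(start_arr[win[0]]),
                    "end": int(start_arr[win[-1]]) + bin_size,
                    "n_cpgs": c,
                    "bin_ids": win,
                }
            )
            placed = True
            break
        if not placed:
            unmatched.append(reg["region_id"])
            log.warning("no matched control found for %s", reg["region_id"])
    return pd.DataFrame(
        controls,
        columns=["region_id", "corsiv_id", "chrom", "start", "end", "n_cpgs", "bin_ids"],
    ), unmatched


# ---------------------------------------------------------------------------
# positional statistics


def subtelomeric_enrichment(
    regions: pd.DataFrame,
    reference: pd.DataFrame,
    chrom_sizes: dict[str, int],
    window_bp: int = 5_000_000,
    test: str = "chi2",
) -> EnrichmentResult:
    """Enrichment of regions lying wholly within ``window_bp`` of either
    chromosome end, relative to a reference region set."""

    def flags(df):
        out = np.zeros(len(df), dtype=bool)
        for k, (chrom, s, e) in enumerate(zip(df["chrom"], df["start"], df["end"])):
            size = chrom_sizes[chrom]
            if e > size:
                raise ValueError(f"region beyond chromosome length: {chrom}:{s}-{e}")
            out[k] = (e <= window_bp) or (s >= size - window_bp)
        return out

    return enrichment_from_flags(
        flags(regions), flags(reference), test=test, feature="subtelomeric"
    )


def ks_uniformity(
    regions: pd.DataFrame, chrom_sizes: dict[str, int]
) -> tuple[float, float]:
    """One-sample KS test of region midpoints against genomic uniformity.

    Midpoints are mapped onto a concatenated genome coordinate normalized to
    [0, 1]; clustered regions give large D and small p.
    """
    if len(regions) < 5:
        raise ValueError("need at least 5 regions")
    offsets = {}
    total = 0
    for chrom, size in chrom_sizes.items():
        offsets[chrom] = total
        total += size
    mids = (
        regions["start"].to_numpy() + regions["end"].to_numpy()
    ) / 2.0 + regions["chrom"].map(offsets).to_numpy()
    u = mids / total
    res = stats.kstest(u, "uniform")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# superCoRSIVs


def find_supercorsivs(
    corsivs: pd.DataFrame,
    pooled_means: np.ndarray,
    r_min: float = 0.71,
    min_span_bp: int = 50_000,
):
    """Distant positively intercorrelated region pairs and their clusters.

    Same-chromosome pairs whose pooled per-individual methylation correlates
    with R >= ``r_min`` across a genomic gap >= ``min_span_bp`` (beyond
    typical haplotype-block scale) are reported, together with their
    single-linkage clusters and cluster spans.
    """
    corsivs = corsivs.reset_index(drop=True)
    pairs = []
    parent = list(range(len(corsivs)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for chrom, grp in corsivs.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                gap = max(
                    corsivs.at[j, "start"] - corsivs.at[i, "end"],
                    corsivs.at[i, "start"] - corsivs.at[j, "end"],
                )
                if gap < min_span_bp:
                    continue
                x, y = pooled_means[i], pooled_means[j]
                ok = ~np.isnan(x) & ~np.isnan(y)
                if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
                    continue
                r = float(np.corrcoef(x[ok], y[ok])[0, 1])
                if r >= r_min:
                    pairs.append(
                        {
                            "region_a": corsivs.at[i, "region_id"],
                            "region_b": corsivs.at[j, "region_id"],
                            "chrom": chrom,
                            "gap_bp": int(gap),
                            "r": r,
                        }
                    )
                    union(i, j)
    pairs_df = pd.DataFrame(
        pairs, columns=["region_a", "region_b", "chrom", "gap_bp", "r"]
    )
    clusters = []
    in_pair = {
        i
        for i in range(len(corsivs))
        if corsivs.at[i, "region_id"]
        in set(pairs_df["region_a"]) | set(pairs_df["region_b"])
    }
    by_root: dict[int, list[int]] = {}
    for i in sorted(in_pair):
        by_root.setdefault(find(i), []).append(i)
    for cid, members in enumerate(v for v in by_root.values() if len(v) > 1):
        sub = corsivs.iloc[members]
        clusters.append(
            {
                "cluster_id": f"super_{cid}",
                "chrom": sub["chrom"].iloc[0],
                "start": int(sub["start"].min()),
                "end": int(sub["end"].max()),
                "n_regions": len(members),
                "members": list(sub["region_id"]),
            }
        )
    clusters_df = pd.DataFrame(
        clusters, columns=["cluster_id", "chrom", "start", "end", "n_regions", "members"]
    )
    return pairs_df, clusters_df


def tad_containment_test(
    spans: pd.DataFrame,
    control_spans: pd.DataFrame,
    tad_sets: dict[str, pd.DataFrame],
):
    """Paired t-test of whole-TAD containment proportions across TAD sets.

    For each (per-tissue) TAD interval set, the proportion of spans lying
    wholly within a single TAD is computed for the cluster spans and for
    matched controls; the per-set proportion differences are tested against
    zero with a paired t-test.  Returns ``(t, p, per_set)``.
    """
    if len(tad_sets) < 2:
        raise ValueError("need at least 2 TAD sets for a paired t-test")

    def contained_fraction(df, tads):
        trees = _trees(tads)
        n = 0
        for chrom, s, e in zip(df["chrom"], df["start"], df["end"]):
            t = trees.get(chrom)
            if t is None:
                continue
            for iv in t.overlap(int(s), int(e)):
                if iv.begin <= s and e <= iv.end:
                    n += 1
                    break
        return n / len(df)

    rows = []
    for name, tads in tad_sets.items():
        ps = contained_fraction(spans, tads)
        pc = contained_fraction(control_spans, tads)
        rows.append({"tad_set": name, "prop_spans": ps, "prop_controls": pc,
                     "diff": ps - pc})
    per_set = pd.DataFrame(rows)
    diffs = per_set["diff"].to_numpy()
    if (diffs == 0).all():
        return float("nan"), float("nan"), per_set
    t, p = stats.ttest_rel(per_set["prop_spans"], per_set["prop_controls"])
    return float(t), float(p), per_set


# ---------------------------------------------------------------------------
# probe mapping


def map_probes_to_regions(
    probes: pd.DataFrame, regions: pd.DataFrame
) -> pd.DataFrame:
    """Assign array probes (single positions) to regions by containment
    (position in [start, end)).  Duplicate probe ids are an error."""
    if probes["probe_id"].duplicated().any():
        raise ValueError("duplicate probe ids")
    trees: dict[str, IntervalTree] = {}
    for _, reg in regions.iterrows():
        trees.setdefault(reg["chrom"], IntervalTree())[
            int(reg["start"]) : int(reg["end"])
        ] = reg["region_id"]
    rows = []
    for pid, chrom, pos in zip(probes["probe_id"], probes["chrom"], probes["pos"]):
        t = trees.get(chrom)
        hits = t[int(pos)] if t is not None else set()
        for iv in hits:
            rows.append({"probe_id": pid, "region_id": iv.data})
        if not hits:
            rows.append({"probe_id": pid, "region_id": None})
    return pd.DataFrame(rows, columns=["probe_id", "region_id"])
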