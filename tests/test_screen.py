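import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import corsiv
from corsiv.binmatrix import BinMatrix
from corsiv.screen import (
    pearson_r,
    build_correlated_regions,
    inter_tissue_correlation,
    itc_screen,
    corsiv_filters,
    cluster_samples,
)
from tests.conftest import truth_region_table


def pooled_bin_matrix(profiles, starts=None, chrom="chr1", n_cpgs=2):
    """BinMatrix with one tissue whose bin percents equal ``profiles`` rows
    exactly (total=1000 reads per bin/sample)."""
    profiles = np.asarray(profiles, dtype=float)
    n_bins, n_ind = profiles.shape
    if starts is None:
        starts = np.arange(n_bins) * 100
    samples = [(f"I{k:02d}", "t1") for k in range(n_ind)]
    total = np.full((n_bins, n_ind), 1000, dtype=np.int64)
    meth = np.round(profiles * 10).astype(np.int64)
    bins = pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": np.asarray(starts) + 100,
         "n_cpgs": n_cpgs}
    )
    return BinMatrix(bins=bins, samples=samples, meth_counts=meth, total_counts=total)


class TestPearson:
    def test_perfect_and_anticorrelation(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_against_direct_formula(self):
        x = np.arange(10.0, 101.0, 10.0)
        y = np.array([12, 18, 35, 38, 52, 58, 71, 79, 93, 99], dtype=float)
        # independent covariance/variance arithmetic
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov / (x.std() * y.std())
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.99670, abs=1e-4)

    def test_constant_vector_undefined(self):
        assert np.isnan(pearson_r(np.ones(5), np.arange(5.0)))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=4, max_size=10),
        st.floats(0.1, 5),
        st.floats(-50, 50),
    )
    def test_affine_invariance(self, xs, a, b):
        x = np.array(xs)
        y = np.linspace(0, 1, len(x)) + np.sin(x)
        r0 = pearson_r(x, y)
        if np.isnan(r0):
            return
        assert pearson_r(a * x + b, y) == pytest.approx(r0, abs=1e-8)


def oracle_regions(pooled, starts, ends, usable, r_min, max_gap, min_bins):
    """Naive reference: greedy scan recomputing the mean profile each step."""
    idx = [i for i in range(len(starts)) if usable[i]]
    out, cur = [], []
    for b in idx:
        if cur:
            gap = starts[b] - ends[cur[-1]]
            mean_prof = np.mean([pooled[i] for i in cur], axis=0)
            r = pearson_r(pooled[b], mean_prof)
            if gap <= max_gap and not np.isnan(r) and r >= r_min:
                cur.append(b)
                continue
            if len(cur) >= min_bins:
                out.append(tuple(cur))
            cur = []
        cur = [b]
    if len(cur) >= min_bins:
        out.append(tuple(cur))
    return out


class TestBuildRegions:
    def test_two_identical_profiles_form_one_region(self):
        prof = np.array([[10, 30, 50, 70], [10, 30, 50, 70.0]])
        bm = pooled_bin_matrix(prof)
        regs = build_correlated_regions(bm, informative=np.ones(2, bool))
        assert len(regs) == 1 and regs.iloc[0]["n_bins"] == 2

    def test_anticorrelated_neighbors_not_joined(self):
        x = np.array([10, 30, 50, 70.0])
        bm = pooled_bin_matrix(np.vstack([x, 80 - x]))
        regs = build_correlated_regions(bm, informative=np.ones(2, bool))
        assert len(regs) == 0

    def test_gap_rule_closes_region(self):
        x = np.array([10, 30, 50, 70.0])
        bm = pooled_bin_matrix(np.vstack([x, x, x]), starts=[0, 100, 300])
        regs = build_correlated_regions(bm, informative=np.ones(3, bool), max_gap_bp=0)
        assert len(regs) == 1 and regs.iloc[0]["n_bins"] == 2
        regs2 = build_correlated_regions(
            bm, informative=np.ones(3, bool), max_gap_bp=100
        )
        assert len(regs2) == 1 and regs2.iloc[0]["n_bins"] == 3

    def test_matches_exhaustive_oracle_on_random_instances(self):
        """Step-wise construction equals the naive reference scan on 200
        random 20-50-bin instances with mixed runs, gaps and noise."""
        rng = np.random.default_rng(99)
        for rep in range(200):
            n_bins = int(rng.integers(20, 51))
            n_ind = 10
            prof = np.empty((n_bins, n_ind))
            b = 0
            while b < n_bins:
                run = int(rng.integers(1, 6))
                run = min(run, n_bins - b)
                base = rng.uniform(10, 90, n_ind)
                for j in range(run):
                    noise = rng.normal(0, rng.uniform(0.5, 15), n_ind)
                    prof[b + j] = np.clip(base + noise, 0, 100)
                b += run
            starts = np.cumsum(rng.choice([100, 100, 100, 200], n_bins)) - 100
            usable = rng.random(n_bins) > 0.1
            bm = pooled_bin_matrix(prof, starts=starts)
            got = build_correlated_regions(
                bm, informative=usable, max_gap_bp=0, min_bins=2
            )
            want = oracle_regions(
                bm.pooled_meth,
                bm.bins["start"].to_numpy(),
                bm.bins["end"].to_numpy(),
                usable,
                0.71,
                0,
                2,
            )
            got_tuples = [tuple(b) for b in got["bin_ids"]]
            assert got_tuples == want, f"replicate {rep}"


class TestITC:
    def _bm_three_tissues(self, per_tissue):
        """One 2-bin region; per_tissue maps tissue -> per-individual percents."""
        n_ind = len(next(iter(per_tissue.values())))
        samples = [
            (f"I{k:02d}", t) for k in range(n_ind) for t in per_tissue
        ]
        n_bins = 2
        meth = np.zeros((n_bins, len(samples)), dtype=np.int64)
        total = np.full((n_bins, len(samples)), 1000, dtype=np.int64)
        for j, (ind, t) in enumerate(samples):
            k = int(ind[1:])
            meth[:, j] = round(per_tissue[t][k] * 10)
        bins = pd.DataFrame(
            {"chrom": "chr1", "start": [0, 100], "end": [100, 200], "n_cpgs": 3}
        )
        return BinMatrix(bins=bins, samples=samples, meth_counts=meth, total_counts=total)

    def test_identical_tissue_profiles_give_unit_itc(self):
        prof = list(np.linspace(10, 80, 10))
        bm = self._bm_three_tissues({"b": prof, "h": prof, "t": prof})
        region = {"bin_ids": np.array([0, 1])}
        itcs, min_itc = inter_tissue_correlation(region, bm)
        assert min_itc == pytest.approx(1.0)
        assert all(v == pytest.approx(1.0) for v in itcs.values())

    def test_permuted_tissue_breaks_itc(self):
        """Scrambling one tissue's individuals destroys the minimum ITC in
        nearly all trials."""
        rng = np.random.default_rng(12)
        broken = 0
        n_trials = 300
        for _ in range(n_trials):
            prof = np.array(rng.uniform(10, 90, 10))
            perm = rng.permutation(prof)
            bm = self._bm_three_tissues(
                {"b": prof, "h": prof, "t": perm}
            )
            _, min_itc = inter_tissue_correlation({"bin_ids": np.array([0, 1])}, bm)
            broken += min_itc < 0.71
        assert broken / n_trials >= 0.95

    def test_itc_threshold_inclusive(self):
        regions = pd.DataFrame(
            {"region_id": ["a", "b"], "min_itc": [0.70, 0.71]}
        )
        kept = itc_screen(regions, itc_min=0.71)
        assert kept["region_id"].tolist() == ["b"]


class TestFilters:
    @pytest.mark.parametrize(
        "n_cpgs,iir,kept",
        [(4, 50.0, False), (8, 19.9, False), (5, 20.0, True), (5, 50.0, True)],
    )
    def test_cpg_and_iir_boundaries(self, n_cpgs, iir, kept):
        cand = pd.DataFrame(
            {"region_id": ["r"], "n_cpgs": [n_cpgs], "iir": [iir], "min_itc": [0.9]}
        )
        out = corsiv_filters(cand)
        assert (len(out) == 1) is kept


class TestClustering:
    def test_identical_samples_join_at_zero_distance(self):
        rng = np.random.default_rng(5)
        prof = rng.uniform(10, 90, size=(20, 1))
        profs = np.hstack([prof, prof, rng.uniform(10, 90, size=(20, 1))])
        bm = pooled_bin_matrix(profs)
        Z, _ = cluster_samples(bm, np.arange(20))
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-9)

    def test_too_few_usable_bins_rejected(self, small_bm):
        with pytest.raises(ValueError):
            cluster_samples(small_bm, np.array([], dtype=int))


class TestScreenProperties:
    def test_threshold_monotonicity(self, small_bm):
        """Raising a filter threshold (CpG count, IIR, ITC) shrinks the call
        set exactly; raising r_min re-partitions the chains, so stricter
        calls must still fall inside previously built candidate regions."""
        base = corsiv.CorsivScreen(small_bm).fit()
        assert len(base.corsivs) > 0
        for kw in [{"min_cpgs": 8}, {"min_iir": 35.0}, {"itc_min": 0.9}]:
            stricter = corsiv.CorsivScreen(small_bm, **kw).fit()
            strict_coords = {
                (r.chrom, r.start, r.end) for r in stricter.corsivs.itertuples()
            }
            base_coords = {
                (r.chrom, r.start, r.end) for r in base.corsivs.itertuples()
            }
            assert strict_coords <= base_coords, kw
            assert len(strict_coords) < len(base_coords), kw
        harder = corsiv.CorsivScreen(small_bm, r_min=0.85).fit()
        for r in harder.corsivs.itertuples():
            overlapping = base.regions[
                (base.regions["chrom"] == r.chrom)
                & (base.regions["start"] < r.end)
                & (base.regions["end"] > r.start)
            ]
            assert len(overlapping) > 0

    def test_individual_relabelling_invariance(self, small_sim, small_bm):
        """Consistently permuting individual order leaves the call set
        unchanged."""
        rng = np.random.default_rng(17)
        inds = small_bm.individuals
        perm = list(rng.permutation(inds))
        reordered = {}
        for (ind, tis), df in small_sim.tables.items():
            reordered[(perm[inds.index(ind)], tis)] = df
        bm2 = corsiv.bin_methylation(reordered)
        a = corsiv.CorsivScreen(small_bm).fit().corsivs
        b = corsiv.CorsivScreen(bm2).fit().corsivs
        coords_a = sorted(zip(a["chrom"], a["start"], a["end"]))
        coords_b = sorted(zip(b["chrom"], b["start"], b["end"]))
        assert coords_a == coords_b

    def test_recovery_on_small_cohort(self, small_sim, small_bm, small_screen):
        truth = truth_region_table(small_sim, small_bm)
        calls = small_screen.corsivs
        sys_rows = truth[truth["cls"].str.startswith("systemic")]
        hit = 0
        for r in sys_rows.itertuples():
            sub = calls[
                (calls["chrom"] == r.chrom)
                & (calls["start"] < r.end)
                & (calls["end"] > r.start)
            ]
            hit += len(sub) > 0
        assert hit / len(sys_rows) >= 0.85

    def test_summary_and_exports(self, small_screen, tmp_path):
        text = small_screen.summary()
        assert "CoRSIVs" in text and str(len(small_screen.corsivs)) in text
        small_screen.to_bed(tmp_path / "c.bed")
        bed = corsiv.read_bed(tmp_path / "c.bed")
        assert len(bed) == len(small_screen.corsivs)
        rid = small_screen.corsivs["region_id"].iloc[0]
        mat = small_screen.corsiv_sample_matrix(rid)
        assert mat.shape == (10, 3)
        assert np.isfinite(mat.to_numpy()).all()
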