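import numpy as np
import pandas as pd
import pytest

import corsiv
from corsiv.context import (
    overlap_flags,
    enrichment_from_flags,
    feature_enrichment,
    sample_matched_controls,
    subtelomeric_enrichment,
    ks_uniformity,
    find_supercorsivs,
    tad_containment_test,
    map_probes_to_regions,
)


def regions_df(triples):
    return pd.DataFrame(triples, columns=["chrom", "start", "end"]).assign(
        region_id=lambda d: [f"r{i}" for i in range(len(d))]
    )


class TestOverlapEngine:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        regions = regions_df(
            [("chr1", int(s), int(s) + int(rng.integers(50, 500)))
             for s in rng.integers(0, 100_000, 300)]
        )
        feats = regions_df(
            [("chr1", int(s), int(s) + int(rng.integers(20, 800)))
             for s in rng.integers(0, 100_000, 300)]
        )
        got = overlap_flags(regions, feats)
        want = np.array(
            [
                any(
                    (f.start < r.end) and (f.end > r.start)
                    for f in feats.itertuples()
                )
                for r in regions.itertuples()
            ]
        )
        np.testing.assert_array_equal(got, want)


class TestEnrichment:
    def test_odds_ratio_direct_arithmetic(self):
        fa = np.array([True] * 30 + [False] * 70)
        fb = np.array([True] * 10 + [False] * 90)
        res = enrichment_from_flags(fa, fb, test="chi2")
        assert res.odds_ratio == pytest.approx((30 * 90) / (70 * 10))
        assert res.odds_ratio == pytest.approx(3.857, abs=1e-3)

    def test_identical_sets_null(self):
        feats = regions_df([("chr1", 0, 100)])
        regs = regions_df([("chr1", 50, 150), ("chr1", 500, 600)])
        res = feature_enrichment(regs, regs, feats, test="fisher")
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_zero_cell_haldane_correction(self):
        fa = np.array([True] * 10)
        fb = np.array([False] * 10)
        res = enrichment_from_flags(fa, fb, test="fisher")
        assert np.isfinite(res.odds_ratio) and res.odds_ratio > 1
        assert 0 < res.p <= 1

    def test_swap_symmetry(self):
        fa = np.array([True] * 30 + [False] * 70)
        fb = np.array([True] * 15 + [False] * 85)
        ab = enrichment_from_flags(fa, fb, test="chi2")
        ba = enrichment_from_flags(fb, fa, test="chi2")
        assert ab.p == pytest.approx(ba.p)
        assert ab.odds_ratio == pytest.approx(1 / ba.odds_ratio)


class TestMatchedControls:
    def test_constraints_hold(self, small_sim, small_bm, small_screen):
        corsivs = small_screen.corsivs
        controls, unmatched = sample_matched_controls(
            corsivs, small_bm.bins, small_screen.informative,
            small_bm.bin_size, seed=3,
        )
        assert len(controls) + len(unmatched) == len(corsivs)
        assert len(controls) >= 0.8 * len(corsivs)
        by_id = corsivs.set_index("region_id")
        for c in controls.itertuples():
            target = by_id.loc[c.corsiv_id]
            assert c.chrom == target["chrom"]
            assert c.end - c.start == target["end"] - target["start"]
            assert abs(c.n_cpgs - target["n_cpgs"]) <= 0.1 * target["n_cpgs"]
        # global disjointness: controls vs controls and vs corsivs
        allregs = pd.concat(
            [controls[["chrom", "start", "end"]], corsivs[["chrom", "start", "end"]]]
        ).sort_values(["chrom", "start"])
        for _, grp in allregs.groupby("chrom"):
            assert (grp["start"].to_numpy()[1:] >= grp["end"].to_numpy()[:-1]).all()

    def test_same_seed_identical(self, small_bm, small_screen):
        kw = dict(
            bins=small_bm.bins, informative=small_screen.informative,
            bin_size=small_bm.bin_size, seed=9,
        )
        a, _ = sample_matched_controls(small_screen.corsivs, **kw)
        b, _ = sample_matched_controls(small_screen.corsivs, **kw)
        pd.testing.assert_frame_equal(
            a.drop(columns="bin_ids"), b.drop(columns="bin_ids")
        )


class TestSubtelomeric:
    SIZES = {"chr1": 100_000_000}

    def test_terminal_region_flagged(self):
        regs = regions_df([("chr1", 0, 300)])
        ref = regions_df([("chr1", 50_000_000, 50_000_300)] * 5)
        res = subtelomeric_enrichment(regs, ref, self.SIZES, window_bp=5_000_000,
                                      test="fisher")
        assert res.table[0, 0] == 1 and res.table[1, 0] == 0

    def test_midpoint_region_not_flagged(self):
        regs = regions_df([("chr1", 50_000_000, 50_000_200)])
        res = subtelomeric_enrichment(
            regs, regions_df([("chr1", 10, 200)]), self.SIZES,
            window_bp=5_000_000, test="fisher",
        )
        assert res.table[0, 0] == 0

    def test_planted_excess_recovered(self):
        """2x planted subtelomeric excess yields an OR near 2."""
        rng = np.random.default_rng(5)
        size = 100_000_000
        win = 5_000_000

        def draw(p_sub, n):
            rows = []
            for _ in range(n):
                if rng.random() < p_sub:
                    s = int(rng.integers(0, win - 200))
                    if rng.random() < 0.5:
                        s = size - s - 200
                else:
                    s = int(rng.integers(win, size - win - 200))
                rows.append(("chr1", s, s + 200))
            return regions_df(rows)

        # reference at the uniform rate (2*win/size = 10%), regions at 20%
        regs = draw(0.20, 1000)
        ref = draw(0.10, 1000)
        res = subtelomeric_enrichment(regs, ref, {"chr1": size}, window_bp=win)
        assert 1.5 <= res.odds_ratio <= 2.7


class TestKsUniformity:
    SIZES = {"chr1": 1_000_000}

    def test_regular_grid_is_uniform(self):
        mids = np.arange(5_000, 1_000_000, 10_000)
        regs = regions_df([("chr1", int(m) - 50, int(m) + 50) for m in mids])
        D, p = ks_uniformity(regs, self.SIZES)
        assert p > 0.99

    def test_identical_midpoints_maximal_deviation(self):
        regs = regions_df([("chr1", 10_000, 10_100)] * 50)
        D, p = ks_uniformity(regs, self.SIZES)
        assert D > 0.95 and p < 1e-10

    def test_uniform_draws_calibrated(self):
        from scipy import stats

        rng = np.random.default_rng(6)
        ps = []
        for _ in range(200):
            s = rng.integers(0, 999_900, 40)
            regs = regions_df([("chr1", int(x), int(x) + 100) for x in s])
            ps.append(ks_uniformity(regs, self.SIZES)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestSuperCorsivs:
    def _coords(self, spans):
        return pd.DataFrame(
            [
                {"region_id": f"r{i}", "chrom": "chr1", "start": s, "end": e}
                for i, (s, e) in enumerate(spans)
            ]
        )

    def test_shared_driver_pair_detected(self):
        rng = np.random.default_rng(7)
        lat = rng.uniform(20, 80, 10)
        pooled = np.vstack([lat + rng.normal(0, 2, 10), lat + rng.normal(0, 2, 10)])
        coords = self._coords([(0, 300), (200_000, 200_300)])
        pairs, clusters = find_supercorsivs(coords, pooled)
        assert len(pairs) == 1 and pairs.iloc[0]["gap_bp"] == 199_700
        assert len(clusters) == 1 and clusters.iloc[0]["n_regions"] == 2

    def test_span_floor_excludes_nearby_pair(self):
        rng = np.random.default_rng(8)
        lat = rng.uniform(20, 80, 10)
        pooled = np.vstack([lat, lat])
        coords = self._coords([(0, 300), (40_000, 40_300)])
        pairs, _ = find_supercorsivs(coords, pooled, min_span_bp=50_000)
        assert len(pairs) == 0

    def test_independent_regions_near_null_rate(self):
        """Detection of unrelated region pairs matches the null probability
        of Pearson R >= 0.71 at n=10."""
        rng = np.random.default_rng(9)
        n = 60
        pooled = rng.uniform(10, 90, (n, 10))
        coords = self._coords([(i * 200_000, i * 200_000 + 300) for i in range(n)])
        pairs, _ = find_supercorsivs(coords, pooled)
        n_pairs = n * (n - 1) / 2
        # null P(R >= .71) at n=10 is ~1.07%  (t-distribution tail)
        from scipy import stats

        t = 0.71 * np.sqrt(8 / (1 - 0.71**2))
        p_null = stats.t.sf(t, df=8)
        rate = len(pairs) / n_pairs
        se = np.sqrt(p_null * (1 - p_null) / n_pairs)
        assert abs(rate - p_null) < 4 * se + 0.005


class TestTadContainment:
    def _tads(self, boundaries):
        return pd.DataFrame(
            [{"chrom": "chr1", "start": s, "end": e} for s, e in boundaries]
        )

    def test_containment_definition(self):
        spans = regions_df([("chr1", 100, 200)])
        inside = self._tads([(50, 250)])
        straddle = self._tads([(150, 400)])
        t, p, per = tad_containment_test(
            spans, spans, {"a": inside, "b": straddle}
        )
        assert per.loc[per["tad_set"] == "a", "prop_spans"].iloc[0] == 1.0
        assert per.loc[per["tad_set"] == "b", "prop_spans"].iloc[0] == 0.0

    def test_constructed_positive_fixture(self):
        rng = np.random.default_rng(10)
        spans = regions_df(
            [("chr1", int(s), int(s) + 5_000) for s in rng.integers(100_000, 900_000, 20)]
        )
        # controls straddle TAD boundaries by construction
        tad_sets = {}
        for k in range(6):
            edges = np.sort(rng.integers(0, 1_000_000, 8))
            tad_sets[f"t{k}"] = self._tads(
                [(0, 1_000_000)]  # everything contained for spans
            )
        controls = regions_df([("chr1", 999_000, 1_200_000)] * 20)
        t, p, per = tad_containment_test(spans, controls, tad_sets)
        assert (per["diff"] > 0).all()
        assert p < 0.05

    def test_identical_sets_degenerate(self):
        spans = regions_df([("chr1", 100, 200)])
        tads = {f"t{k}": self._tads([(0, 1000)]) for k in range(3)}
        t, p, per = tad_containment_test(spans, spans, tads)
        assert np.isnan(p)

    def test_fewer_than_two_sets_rejected(self):
        spans = regions_df([("chr1", 100, 200)])
        with pytest.raises(ValueError):
            tad_containment_test(spans, spans, {"only": self._tads([(0, 1000)])})


class TestProbeMapping:
    def test_boundary_conventions(self):
        regions = regions_df([("chr1", 100, 200)])
        probes = pd.DataFrame(
            {"probe_id": ["pA", "pB", "pC"], "chrom": "chr1",
             "pos": [100, 199, 200]}
        )
        got = map_probes_to_regions(probes, regions)
        assigned = got.dropna(subset=["region_id"])
        assert set(assigned["probe_id"]) == {"pA", "pB"}

    def test_duplicate_probe_ids_rejected(self):
        regions = regions_df([("chr1", 100, 200)])
        probes = pd.DataFrame(
            {"probe_id": ["p", "p"], "chrom": "chr1", "pos": [110, 120]}
        )
        with pytest.raises(ValueError):
            map_probes_to_regions(probes, regions)

    def test_matches_linear_scan(self):
        rng = np.random.default_rng(11)
        regions = regions_df(
            [("chr1", int(s), int(s) + int(rng.integers(100, 400)))
             for s in np.sort(rng.choice(np.arange(0, 200_000, 500), 50, replace=False))]
        )
        probes = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(500)],
                "chrom": "chr1",
                "pos": rng.integers(0, 200_000, 500),
            }
        )
        got = map_probes_to_regions(probes, regions)
        lookup = got.dropna(subset=["region_id"]).groupby("probe_id")["region_id"].apply(set)
        for p in probes.itertuples():
            want = {
                r.region_id
                for r in regions.itertuples()
                if r.start <= p.pos < r.end
            }
            have = lookup.get(p.probe_id, set())
            assert have == want
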