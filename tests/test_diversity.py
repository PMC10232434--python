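import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riveredith import diversity as dv
from riveredith.errors import (BinningError, InsufficientDataError,
                               UndefinedGroupError)
from riveredith.network import (accumulate_drainage_area, build_network,
                                flow_connected)

from conftest import random_tree_records


def reads_table(rows):
    return pd.DataFrame(rows, columns=["site_id", "genus", "season", "reads"])


class TestContaminationFilter:
    def test_subtraction_rule(self):
        t = reads_table([("s1", "g1", "spring", 50),
                         ("s1", "g2", "spring", 950)])
        out = dv.contamination_filter(t, 0.001)
        assert out["reads"].tolist() == [49, 949]

    def test_clamp_at_zero(self):
        t = reads_table([("s1", "g1", "spring", 1),
                         ("s1", "g2", "spring", 999)])
        out = dv.contamination_filter(t, 0.001)
        assert out["reads"].tolist() == [0, 998]

    def test_empty_sample_unchanged(self):
        t = reads_table([("s1", "g1", "spring", 0)])
        out = dv.contamination_filter(t, 0.001)
        assert out["reads"].tolist() == [0]

    def test_per_sample_totals(self):
        # two samples: the cut is computed within each (site, season)
        t = reads_table([("s1", "g1", "spring", 100),
                         ("s2", "g1", "spring", 10_000),
                         ("s1", "g1", "summer", 3_000)])
        out = dv.contamination_filter(t, 0.01)
        assert out["reads"].tolist() == [99, 9_900, 2_970]

    def test_threshold_mode(self):
        t = reads_table([("s1", "g1", "spring", 5),
                         ("s1", "g2", "spring", 9_995)])
        out = dv.contamination_filter(t, 0.001, mode="threshold")
        assert out["reads"].tolist() == [0, 9_995]


class TestRichness:
    def test_counts_and_bound(self):
        pres = pd.DataFrame({"g1": [True, False], "g2": [True, True],
                             "g3": [False, False]}, index=["r1", "r2"])
        r = dv.richness(pres)
        assert r.tolist() == [2, 1]
        assert (r <= 3).all()

    def test_all_absent(self):
        pres = pd.DataFrame({"g1": [False], "g2": [False]}, index=["r1"])
        assert dv.richness(pres).tolist() == [0]

    def test_raw_richness_presence_only(self):
        t = reads_table([("s1", "g1", "spring", 5), ("s1", "g2", "spring", 0),
                         ("s1", "g3", "spring", 2), ("s2", "g1", "spring", 0),
                         ("s1", "g1", "summer", 99)])
        r = dv.raw_richness(t, ["g1", "g2", "g3"], "spring")
        assert r["s1"] == 2 and r["s2"] == 0
        # magnitudes do not matter
        t2 = t.assign(reads=t["reads"] * 1000)
        assert dv.raw_richness(t2, ["g1", "g2", "g3"], "spring").equals(r)


class TestRegressOnArea:
    def test_exact_line(self):
        areas = np.array([1.0, 2.0, 3.0, 4.0])
        res = dv.regress_on_area(2 * areas + 1, areas)
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_values(self):
        res = dv.regress_on_area([5, 5, 5, 5], [1, 2, 3, 4])
        assert res.slope == pytest.approx(0.0)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(1, 10, 20)
        v = 3 * a + rng.normal(size=20)
        r1 = dv.regress_on_area(v, a)
        perm = rng.permutation(20)
        r2 = dv.regress_on_area(v[perm], a[perm])
        assert r1.slope == pytest.approx(r2.slope)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            dv.regress_on_area([1, 2], [1, 2])


class TestBootstrapTrendTest:
    @staticmethod
    def _areas(n=500, seed=0):
        return np.exp(np.random.default_rng(seed).uniform(0, 5, n))

    def test_noiseless_increasing(self):
        a = self._areas()
        res = dv.bootstrap_trend_test(a.copy(), a, seed=1)
        assert res.n_positive == 100
        assert res.verdict == "positive-significant"

    def test_noiseless_decreasing(self):
        a = self._areas()
        res = dv.bootstrap_trend_test(-a, a, seed=1)
        assert res.n_positive == 0
        assert res.verdict == "negative-significant"

    def test_null_rarely_significant(self):
        a = self._areas(1908, seed=3)
        rng = np.random.default_rng(4)
        n_sig = sum(
            dv.bootstrap_trend_test(rng.normal(size=1908), a, seed=k).verdict
            != "non-significant" for k in range(20))
        assert n_sig <= 2

    def test_ci_band_brackets_fit(self):
        a = self._areas()
        rng = np.random.default_rng(5)
        v = 0.5 * a + rng.normal(scale=5, size=a.size)
        res = dv.bootstrap_trend_test(v, a, seed=6)
        fit = res.slope * res.area_grid + res.intercept
        # the band is an envelope of resampled fits around the full fit
        assert np.all(res.ci_low <= res.ci_high)
        assert np.mean((fit >= res.ci_low) & (fit <= res.ci_high)) > 0.8

    def test_empty_bin_raises(self):
        with pytest.raises(BinningError):
            dv.bootstrap_trend_test(np.ones(50), np.ones(50), seed=0)


class TestMedianSplit:
    def test_even_split(self):
        net = build_network([("a", "d", 100, 1.0), ("b", "d", 100, 2.0),
                             ("c", "d", 100, 3.0), ("d", None, 100, 0.0)])
        # drainage areas: a=1, b=2, c=3, d=6 → median 2.5
        accumulate_drainage_area(net)
        groups = dv.split_by_median_area(net)
        assert sorted(groups["upstream"]) == ["a", "b"]
        assert sorted(groups["downstream"]) == ["c", "d"]

    def test_ties_go_downstream(self):
        net = build_network([("a", "b", 100, 1.0), ("b", None, 100, 0.0)])
        accumulate_drainage_area(net)  # both areas 1.0 → median 1.0
        groups = dv.split_by_median_area(net)
        assert groups["upstream"] == []
        assert sorted(groups["downstream"]) == ["a", "b"]

    def test_partition_property(self):
        rng = np.random.default_rng(8)
        net = build_network(random_tree_records(31, rng))
        accumulate_drainage_area(net)
        g = dv.split_by_median_area(net)
        assert len(g["upstream"]) + len(g["downstream"]) == 31


class TestPairSelection:
    def test_chain_has_no_pairs(self):
        net = build_network([("a", "b", 100, 1), ("b", "c", 100, 1),
                             ("c", None, 100, 1)])
        assert dv.select_flow_unconnected_pairs(net, ["a", "b", "c"], 0) == []

    def test_y_headwaters_pair(self, y_network):
        pairs = dv.select_flow_unconnected_pairs(y_network, ["h1", "h2"], 0)
        assert len(pairs) == 1
        assert sorted(pairs[0]) == ["h1", "h2"]

    def test_star_perfect_matching(self):
        net = build_network([(f"h{k}", "c", 100, 1) for k in range(4)]
                            + [("c", None, 100, 1)])
        ids = [f"h{k}" for k in range(4)]
        pairs = dv.select_flow_unconnected_pairs(net, ids, 1)
        assert len(pairs) == 2
        used = sorted(x for p in pairs for x in p)
        assert used == sorted(ids)

    @given(st.integers(0, 500))
    @settings(max_examples=40, deadline=None)
    def test_matching_contract(self, seed):
        rng = np.random.default_rng(seed)
        net = build_network(random_tree_records(int(rng.integers(4, 25)), rng))
        ids = list(rng.choice(net.reach_ids,
                              size=int(rng.integers(2, len(net) + 1)),
                              replace=False))
        pairs = dv.select_flow_unconnected_pairs(net, ids, int(seed))
        used = [x for p in pairs for x in p]
        assert len(used) == len(set(used))            # no id reused
        for a, b in pairs:
            assert not flow_connected(net, a, b)      # valid pairs
        unused = set(ids) - set(used)                 # maximality
        for a in unused:
            for b in unused:
                if a != b:
                    assert flow_connected(net, a, b)


class TestJaccard:
    def test_identical_sets(self):
        d = dv.jaccard_decompose(3, 0, 0)
        assert (d.total, d.turnover, d.nestedness) == (0.0, 0.0, 0.0)

    def test_pure_turnover(self):
        d = dv.jaccard_decompose(2, 1, 1)
        assert d.total == pytest.approx(0.5)
        assert d.turnover == pytest.approx(0.5)
        assert d.nestedness == pytest.approx(0.0)

    def test_pure_nestedness(self):
        d = dv.jaccard_decompose(2, 2, 0)
        assert d.total == pytest.approx(0.5)
        assert d.turnover == pytest.approx(0.0)
        assert d.nestedness == pytest.approx(0.5)

    def test_both_empty_undefined(self):
        with pytest.raises(ValueError):
            dv.jaccard_decompose(0, 0, 0)

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=200, deadline=None)
    def test_partition_identity_and_set_oracle(self, a, b, c):
        if a + b + c == 0:
            return
        d = dv.jaccard_decompose(a, b, c)
        assert d.turnover + d.nestedness == pytest.approx(d.total, abs=1e-12)
        assert 0 <= d.turnover <= 1 and 0 <= d.nestedness <= 1
        # set-theoretic oracle: 1 − |∩|/|∪|
        s1 = set(range(a + b))
        s2 = set(range(a)) | set(range(a + b, a + b + c))
        expected = 1 - len(s1 & s2) / len(s1 | s2)
        assert d.total == pytest.approx(expected, abs=1e-12)


class TestSpatialBeta:
    @staticmethod
    def _net():
        # two headwater stars joined deep: plenty of unconnected pairs
        recs = [(f"u{k}", "m1", 100, 1.0) for k in range(4)]
        recs += [(f"d{k}", "m2", 100, 5.0) for k in range(4)]
        recs += [("m1", "m2", 100, 1.0), ("m2", None, 100, 1.0)]
        net = build_network(recs)
        return accumulate_drainage_area(net)

    def test_identical_communities_non_significant(self):
        net = self._net()
        pres = pd.DataFrame(True, index=net.reach_ids, columns=["g1", "g2"])
        res = dv.spatial_beta_test(pres, net, reps=20, seed=0)
        for g, vals in res.group_means.items():
            assert np.allclose(vals, 0.0)
        assert not res.significant

    def test_extreme_groups_significant(self):
        net = self._net()
        genera = [f"g{k}" for k in range(8)]
        pres = pd.DataFrame(False, index=net.reach_ids, columns=genera)
        # upstream u* reaches: pairwise disjoint singletons → Jaccard 1
        for k in range(4):
            pres.loc[f"u{k}", f"g{k}"] = True
        # downstream reaches: all share the same community → Jaccard 0
        for rid in ("d0", "d1", "d2", "d3", "m1", "m2"):
            pres.loc[rid, "g7"] = True
        groups = {"upstream": [f"u{k}" for k in range(4)],
                  "downstream": ["d0", "d1", "d2", "d3"]}
        res = dv.spatial_beta_test(pres, net, reps=20, seed=1, groups=groups)
        assert np.allclose(res.group_means["upstream"], 1.0)
        assert np.allclose(res.group_means["downstream"], 0.0)
        assert res.significant and res.direction == "upstream"

    def test_means_bounded(self, scenario):
        season = "spring"
        res = dv.spatial_beta_test(scenario.true_presence[season],
                                   scenario.network, reps=10, seed=2)
        for vals in res.group_means.values():
            assert np.all((vals >= 0) & (vals <= 1))

    def test_all_empty_group_raises(self):
        net = self._net()
        pres = pd.DataFrame(False, index=net.reach_ids, columns=["g1"])
        with pytest.raises(UndefinedGroupError):
            dv.spatial_beta_test(pres, net, reps=5, seed=0)


class TestTemporalBeta:
    def test_identical_seasons_zero(self):
        pres = pd.DataFrame({"g1": [True, False], "g2": [True, True]},
                            index=["r1", "r2"])
        tb = dv.temporal_beta(pres, pres)
        assert np.allclose(tb.loc[tb["defined"], "total"], 0.0)

    def test_partial_overlap(self):
        a = pd.DataFrame({"X": [True], "Y": [True], "Z": [False]}, index=["r"])
        b = pd.DataFrame({"X": [False], "Y": [True], "Z": [True]}, index=["r"])
        tb = dv.temporal_beta(a, b)
        assert tb.loc["r", "total"] == pytest.approx(2 / 3)

    def test_disappearance_is_nestedness(self):
        a = pd.DataFrame({"X": [True]}, index=["r"])
        b = pd.DataFrame({"X": [False]}, index=["r"])
        tb = dv.temporal_beta(a, b)
        assert tb.loc["r", "total"] == pytest.approx(1.0)
        assert tb.loc["r", "turnover"] == pytest.approx(0.0)
        assert tb.loc["r", "nestedness"] == pytest.approx(1.0)

    def test_empty_both_seasons_undefined(self):
        a = pd.DataFrame({"X": [False, True]}, index=["r1", "r2"])
        tb = dv.temporal_beta(a, a)
        assert not tb.loc["r1", "defined"]
        assert np.isnan(tb.loc["r1", "total"])


class TestPredictedVsRaw:
    def test_identical_samples(self):
        t, p, d = dv.compare_predicted_vs_raw([1, 1, 1], [1, 1, 1])
        assert (t, p, d) == (0.0, 1.0, 0.0)

    def test_large_effect(self):
        rng = np.random.default_rng(0)
        t, p, d = dv.compare_predicted_vs_raw(rng.normal(10, 1, 100),
                                              rng.normal(0, 1, 100))
        assert p < 1e-10 and d == pytest.approx(10, abs=0.5)

    def test_swap_flips_sign(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(2, 1, 50), rng.normal(0, 1, 50)
        t1, p1, _ = dv.compare_predicted_vs_raw(x, y)
        t2, p2, _ = dv.compare_predicted_vs_raw(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestCrossSeason:
    def test_identical_seasons(self):
        pres = pd.DataFrame({"g1": [True, False, True],
                             "g2": [False, True, True]},
                            index=["r1", "r2", "r3"])
        corr, overlap = dv.cross_season_summaries({"a": pres, "b": pres})
        assert np.allclose(corr, 1.0)
        assert overlap["g1"] == pytest.approx(1.0)

    def test_disjoint_occupancies(self):
        a = pd.DataFrame({"g1": [True, False]}, index=["r1", "r2"])
        b = pd.DataFrame({"g1": [False, True]}, index=["r1", "r2"])
        _, overlap = dv.cross_season_summaries({"a": a, "b": b})
        assert overlap["g1"] == pytest.approx(0.0)

    def test_partial_overlap_counting(self):
        idx = [f"r{k}" for k in range(60)]
        stable = pd.Series([k < 30 for k in range(60)], index=idx)
        a = pd.DataFrame({"g1": stable | pd.Series([30 <= k < 45 for k in range(60)], index=idx)})
        b = pd.DataFrame({"g1": stable | pd.Series([45 <= k < 60 for k in range(60)], index=idx)})
        _, overlap = dv.cross_season_summaries({"a": a, "b": b})
        assert overlap["g1"] == pytest.approx(30 / 60)

    def test_genus_order_invariance(self, scenario):
        pres = scenario.true_presence
        corr1, _ = dv.cross_season_summaries(pres)
        rev = {s: p[p.columns[::-1]] for s, p in pres.items()}
        corr2, _ = dv.cross_season_summaries(rev)
        assert np.allclose(corr1.to_numpy(), corr2.to_numpy())
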