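"""Weighted exposure statistics: means, clustered inference, tallies, KDE."""

import numpy as np
import pandas as pd
import pytest

import heat_equity as he
from heat_equity.demographics import DemographicTable
from heat_equity.exposure import EmptyGroupError, significance_stars


def tiny_tables(x, wa, wb, cities):
    """Assemble SUHI frame + two-group demographics from parallel arrays."""
    ids = [f"t{i}" for i in range(len(x))]
    suhi = pd.DataFrame({"tract_id": ids, "urbanized_area_id": cities,
                         "lst_t": np.asarray(x) + 28.0, "lst_r": 28.0,
                         "suhi": x, "n_cells": 4})
    counts = pd.DataFrame({"ga": wa, "gb": wb,
                           "total_pop": np.asarray(wa) + np.asarray(wb)},
                          index=pd.Index(ids, name="tract_id"))
    return suhi, DemographicTable(counts, "toy")


def sandwich_oracle(y, g, w, clusters=None):
    """Hand-coded WLS + CR1/HC1 sandwich for the group-indicator regression."""
    X = np.column_stack([np.ones_like(y), g])
    XtWX = X.T @ (w[:, None] * X)
    bread = np.linalg.inv(XtWX)
    beta = bread @ (X.T @ (w * y))
    u = y - X @ beta
    n, k = X.shape
    if clusters is None:
        meat = (X * ((w * u) ** 2)[:, None]).T @ X
        V = bread @ meat @ bread * n / (n - k)
    else:
        labels = np.unique(clusters)
        G = len(labels)
        meat = np.zeros((k, k))
        for lab in labels:
            m = clusters == lab
            s = (w[m] * u[m]) @ X[m]
            meat += np.outer(s, s)
        c = G / (G - 1) * (n - 1) / (n - k)
        V = bread @ meat @ bread * c
    return beta[1], np.sqrt(V[1, 1])


class TestWeightedMean:
    def test_symmetric_two_tracts(self):
        suhi, demo = tiny_tables([1.0, 3.0], [100, 100], [0, 0], ["U", "U"])
        s = he.weighted_group_mean(suhi, demo, "ga")
        assert s.weighted_mean == 2.0

    def test_degenerate_point_mass(self):
        suhi, demo = tiny_tables([2.5, 0.0], [50, 0], [0, 1], ["U", "U"])
        s = he.weighted_group_mean(suhi, demo, "ga")
        assert (s.weighted_mean, s.weighted_sd) == (2.5, 0.0)

    def test_matches_loop_oracle(self, panel_tables):
        suhi, tables, _ = panel_tables
        demo = tables["income"]
        s = he.weighted_group_mean(suhi, demo, "below_poverty")
        joined = suhi.merge(demo.counts, left_on="tract_id", right_index=True)
        num = den = ss = 0.0
        for row in joined.itertuples():
            num += row.below_poverty * row.suhi
            den += row.below_poverty
        mean = num / den
        for row in joined.itertuples():
            ss += row.below_poverty * (row.suhi - mean) ** 2
        assert s.weighted_mean == pytest.approx(mean, abs=1e-12)
        assert s.weighted_sd == pytest.approx(np.sqrt(ss / den), abs=1e-12)

    def test_empty_group_signals_scope(self):
        suhi, demo = tiny_tables([1.0], [0], [5], ["U"])
        with pytest.raises(EmptyGroupError, match="ga"):
            he.weighted_group_mean(suhi, demo, "ga")

    def test_partition_combining_identity(self, panel_tables):
        # Total-population mean == share-weighted combination of group means.
        suhi, tables, _ = panel_tables
        demo = tables["income"]
        total = he.weighted_group_mean(suhi, demo, "total_pop")
        parts = [he.weighted_group_mean(suhi, demo, g)
                 for g in ("below_poverty", "pov_1to2", "above_2x_poverty")]
        combined = (sum(p.weighted_mean * p.total_weight for p in parts)
                    / sum(p.total_weight for p in parts))
        assert combined == pytest.approx(total.weighted_mean, abs=1e-9)


class TestGroupMeanDifference:
    def test_disjoint_groups_exact_separation(self):
        suhi, demo = tiny_tables([1.0, 3.0], [100, 0], [0, 100], ["U", "V"])
        d = he.group_mean_difference(suhi, demo, "gb", "ga")
        assert d.diff == pytest.approx(2.0, abs=1e-12)

    def test_identical_groups_null(self):
        suhi, demo = tiny_tables([1.0, 3.0, 2.0, 4.0], [10, 20, 30, 40],
                                 [10, 20, 30, 40], ["U", "U", "V", "V"])
        d = he.group_mean_difference(suhi, demo, "ga", "gb")
        assert d.diff == pytest.approx(0.0, abs=1e-12)
        assert d.p_value == pytest.approx(1.0, abs=1e-9)

    def test_regression_equals_direct_difference(self, panel_tables):
        suhi, tables, zone_labels = panel_tables
        for scheme, a, b in [("race", "people_of_color", "nh_white"),
                             ("income", "below_poverty", "above_2x_poverty"),
                             ("age", "under_5", "over_65")]:
            demo = tables[scheme]
            d = he.group_mean_difference(suhi, demo, a, b)
            direct = (he.weighted_group_mean(suhi, demo, a).weighted_mean
                      - he.weighted_group_mean(suhi, demo, b).weighted_mean)
            assert d.diff == pytest.approx(direct, abs=1e-9)

    def test_clustered_se_matches_sandwich_oracle(self, panel_tables):
        suhi, tables, _ = panel_tables
        demo = tables["race"]
        d = he.group_mean_difference(suhi, demo, "people_of_color", "nh_white")
        joined = suhi.merge(demo.counts, left_on="tract_id", right_index=True)
        y = np.concatenate([joined.suhi, joined.suhi])
        g = np.concatenate([np.ones(len(joined)), np.zeros(len(joined))])
        w = np.concatenate([joined.people_of_color, joined.nh_white])
        cl = np.concatenate([joined.urbanized_area_id, joined.urbanized_area_id])
        keep = w > 0
        diff, se = sandwich_oracle(y[keep], g[keep], w[keep], cl[keep])
        assert d.diff == pytest.approx(diff, abs=1e-9)
        assert d.se == pytest.approx(se, rel=1e-6)
        assert d.n_clusters == joined.urbanized_area_id.nunique()
        assert d.df == d.n_clusters - 1

    def test_clustered_se_consistent_with_cluster_bootstrap(self, panel_tables):
        suhi, tables, _ = panel_tables
        demo = tables["race"]
        d = he.group_mean_difference(suhi, demo, "people_of_color", "nh_white")
        rng = np.random.default_rng(2024)
        cities = suhi["urbanized_area_id"].unique()
        boot = []
        joined = suhi.merge(demo.counts, left_on="tract_id", right_index=True)
        for _ in range(1000):
            draw = rng.choice(cities, size=len(cities), replace=True)
            parts = [joined[joined.urbanized_area_id == c] for c in draw]
            res = pd.concat(parts)
            wa, wb = res.people_of_color.to_numpy(), res.nh_white.to_numpy()
            x = res.suhi.to_numpy()
            boot.append((wa * x).sum() / wa.sum() - (wb * x).sum() / wb.sum())
        boot_se = np.std(boot, ddof=1)
        assert d.se == pytest.approx(boot_se, rel=0.15)

    def test_clustered_reduces_to_hc_with_singleton_clusters(self):
        # Disjoint groups, one tract per city: every cluster carries exactly
        # one stacked observation, so CR1 collapses to the HC1 sandwich.
        rng = np.random.default_rng(5)
        n = 16
        x = rng.normal(2, 1, n)
        wa = np.where(np.arange(n) % 2 == 0, rng.integers(50, 200, n), 0)
        wb = np.where(np.arange(n) % 2 == 1, rng.integers(50, 200, n), 0)
        suhi, demo = tiny_tables(x, wa, wb, [f"C{i}" for i in range(n)])
        d = he.group_mean_difference(suhi, demo, "ga", "gb")
        keep_y = np.concatenate([x[wa > 0], x[wb > 0]])
        keep_g = np.concatenate([np.ones((wa > 0).sum()), np.zeros((wb > 0).sum())])
        keep_w = np.concatenate([wa[wa > 0], wb[wb > 0]]).astype(float)
        _, se_hc1 = sandwich_oracle(keep_y, keep_g, keep_w, clusters=None)
        assert d.se == pytest.approx(se_hc1, rel=1e-9)
        assert d.se >= 0

    def test_single_cluster_falls_back_with_warning(self):
        suhi, demo = tiny_tables([1.0, 3.0], [10, 20], [20, 10], ["U", "U"])
        with pytest.warns(UserWarning, match="single cluster"):
            d = he.group_mean_difference(suhi, demo, "ga", "gb")
        assert np.isfinite(d.se)


class TestCityLevelTest:
    def test_identical_occupancy_not_significant(self):
        suhi, demo = tiny_tables([1.0, 3.0], [10, 20], [10, 20], ["U", "U"])
        t = he.city_level_test(suhi, demo, "ga", "gb", "U")
        assert t.diff == pytest.approx(0.0, abs=1e-12)
        assert not t.significant

    def test_full_separation_significant(self):
        suhi, demo = tiny_tables([0.0, 4.0], [500, 0], [0, 500], ["U", "U"])
        t = he.city_level_test(suhi, demo, "gb", "ga", "U")
        assert t.diff == pytest.approx(4.0, abs=1e-12)
        assert t.p_value < 1e-6

    def test_absent_group_marked_not_comparable(self):
        suhi, demo = tiny_tables([1.0, 2.0], [10, 10], [0, 0], ["U", "U"])
        t = he.city_level_test(suhi, demo, "ga", "gb", "U")
        assert not t.comparable
        assert not t.significant

    def test_sign_matches_generator_truth(self, small_config):
        # With a positive disparity slope the estimated per-city gap should
        # carry the generator's sign in nearly every seed.
        hits = trials = 0
        for seed in range(40):
            city = he.generate_city(small_config, seed)
            demo = he.build_groups(city.demographics, he.default_schemes()["race"])
            suhi = he.records_to_frame(
                he.compute_city_suhi(city.landcover, city.lst, city.zones, city.ua_id))
            t = he.city_level_test(suhi, demo, "people_of_color", "nh_white", city.ua_id)
            truth = he.truth_disparity(city, "people_of_color", "nh_white")
            trials += 1
            hits += (t.diff > 0) == (truth > 0)
        assert hits / trials >= 0.95


class TestTalliesAndThresholds:
    def test_tally_counts_and_hand_enumeration(self, panel_tables):
        suhi, tables, zone_labels = panel_tables
        demo = tables["race"]
        cities = sorted(suhi.urbanized_area_id.unique())
        tests = [he.city_level_test(suhi, demo, "people_of_color", "nh_white", c)
                 for c in cities]
        tally = he.tally_city_comparisons(tests, zone_labels)
        nat = tally[tally.scope == "national"].iloc[0]
        assert nat.n_cities == len(cities)
        assert nat.n_a_worse == sum(t.diff > 0 for t in tests)
        assert nat.n_a_worse_sig == sum(t.diff > 0 and t.p_value < 0.05 for t in tests)
        zones_in_table = set(tally.scope) - {"national"}
        assert zones_in_table <= set(zone_labels.values())

    def test_all_positive_gives_full_proportion(self):
        tests = [he.MeanDifference("a", "b", "city", f"C{i}", 0.5, 0.1, 0.001,
                                   "***", 10, 0) for i in range(10)]
        tally = he.tally_city_comparisons(tests)
        assert tally.iloc[0].prop_a_worse == 1.0

    def test_threshold_count_strict(self):
        assert he.cities_above_threshold([1.9, 2.1, 2.0], 2.0) == 1
        assert he.cities_above_threshold([], 2.0) == 0


class TestDensity:
    def test_unscaled_integrates_to_one(self):
        rng = np.random.default_rng(8)
        curve = he.exposure_density(rng.normal(2, 1, 175))
        area = np.trapezoid(curve.density, curve.grid)
        assert area == pytest.approx(1.0, abs=1e-3)

    def test_scaled_area_equals_city_count(self):
        rng = np.random.default_rng(9)
        curve = he.exposure_density(rng.normal(2, 1, 175), n_cities=175)
        area = np.trapezoid(curve.scaled, curve.grid)
        assert area == pytest.approx(175.0, abs=0.2)

    def test_kernel_decay_in_far_tail(self):
        data = np.array([0.0, 0.1, 0.2, 1.9, 2.0, 2.1])
        near = he.exposure_density(data)
        far_grid = np.linspace(data.min() - 12 * near.bandwidth,
                               data.min() - 8 * near.bandwidth, 16)
        far = he.exposure_density(data, grid=far_grid)
        assert far.density.max() < 1e-6 * near.density.max()

    def test_degenerate_spike_warns(self):
        with pytest.warns(UserWarning, match="spike"):
            curve = he.exposure_density(np.array([2.0, 2.0, 2.0]))
        # Essentially all mass collapses into a narrow spike at 2.0.
        assert curve.bandwidth < 1e-4
        assert np.trapezoid(curve.density, curve.grid) == pytest.approx(1.0, abs=0.01)


def test_significance_star_thresholds():
    assert significance_stars(0.005) == "***"
    assert significance_stars(0.03) == "**"
    assert significance_stars(0.07) == "*"
    assert significance_stars(0.2) == ""
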