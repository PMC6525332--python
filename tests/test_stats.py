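"""Group aggregation and the t / ANOVA+Tukey / KS comparisons."""

import numpy as np
import pytest

from zfnet import (
    anova_tukey,
    group_average,
    ks_compare,
    per_threshold_ttest,
    pool_edge_weights,
)
from zfnet.network import CorrelationNetwork, MetricCurve
from zfnet.oracles import brute_ks_statistic
from zfnet.stats import StatsError
from .conftest import make_dataset


def curve(values, grid=None, larva_id=""):
    values = np.asarray(values, float)
    grid = np.arange(values.size, dtype=float) if grid is None else np.asarray(grid)
    return MetricCurve(grid=grid, values=values, metric="m", larva_id=larva_id)


class TestGroupAverage:
    def test_mean_and_sem(self):
        s = group_average([curve([1.0]), curve([3.0])])
        assert s.mean[0] == 2.0
        assert s.sem[0] == pytest.approx(1.0)  # sd = √2, √2/√2 = 1
        assert s.n[0] == 2

    def test_single_larva_sem_flagged(self):
        s = group_average([curve([5.0, 7.0])])
        assert np.array_equal(s.mean, [5.0, 7.0])
        assert np.all(np.isnan(s.sem))

    def test_identical_curves_zero_sem(self):
        s = group_average([curve([1.0, 2.0])] * 5)
        assert np.allclose(s.sem, 0.0)

    def test_missing_cells_excluded(self):
        s = group_average([curve([1.0, np.nan]), curve([3.0, 4.0])])
        assert s.mean[1] == 4.0 and s.n[1] == 1

    def test_mismatched_grids_rejected(self):
        with pytest.raises(StatsError, match="grid"):
            group_average([curve([1.0], grid=[0.0]), curve([1.0], grid=[0.5])])

    def test_sem_scales_inverse_sqrt_n(self, rng):
        vals = rng.standard_normal(64)
        s4 = group_average([curve([v]) for v in vals[:16]])
        s64 = group_average([curve([v]) for v in vals])
        # same underlying spread: SEM shrinks roughly by 2 going 16 → 64
        assert s64.sem[0] < s4.sem[0]


class TestPerThresholdTTest:
    def test_identical_groups(self):
        g = [curve([1.0, 2.0]), curve([3.0, 1.0]), curve([2.0, 0.5])]
        res = per_threshold_ttest(g, [curve(c.values.copy()) for c in g])
        assert np.allclose(res.table["statistic"], 0.0)
        assert np.allclose(res.table["p"], 1.0)

    def test_hand_computed_pooled_t(self):
        # A={1,2,3}, B={4,5,6}: pooled s²=1, SE=√(2/3), t=−3/0.8165=−3.674,
        # df=4 → two-sided p ≈ 0.0214 (published t-table value)
        res = per_threshold_ttest(
            [curve([1.0]), curve([2.0]), curve([3.0])],
            [curve([4.0]), curve([5.0]), curve([6.0])])
        assert res.table["statistic"][0] == pytest.approx(-3.674, abs=1e-3)
        assert res.table["p"][0] == pytest.approx(0.0214, abs=5e-4)
        assert res.table["n_a"][0] == 3 and res.table["n_b"][0] == 3

    def test_zero_variance_flagged(self):
        res = per_threshold_ttest(
            [curve([1.0]), curve([1.0])], [curve([2.0]), curve([2.0])])
        assert res.table["flag"][0] == "degenerate_zero_variance"
        assert res.table["p"][0] < 1e-6

    def test_insufficient_n_is_missing_cell(self):
        res = per_threshold_ttest(
            [curve([1.0, np.nan]), curve([2.0, np.nan])],
            [curve([4.0, 1.0]), curve([5.0, 2.0])])
        assert np.isnan(res.table["p"][1])
        assert res.table["flag"][1] == "insufficient_n"
        assert res.n_tests == 1

    def test_welch_option_differs_under_unequal_variance(self, rng):
        a = [curve([v]) for v in rng.normal(0, 0.1, 6)]
        b = [curve([v]) for v in rng.normal(1, 3.0, 6)]
        student = per_threshold_ttest(a, b, equal_var=True)
        welch = per_threshold_ttest(a, b, equal_var=False)
        assert student.table["p"][0] != welch.table["p"][0]


class TestAnovaTukey:
    def test_identical_groups_f_zero(self):
        res = anova_tukey({3: [1, 2, 3], 4: [1, 2, 3], 5: [1, 2, 3]})
        assert res.table["statistic"][0] == pytest.approx(0.0, abs=1e-12)
        assert res.table["p"][0] == pytest.approx(1.0)
        assert res.extra["tukey"] is None

    def test_tukey_flags_only_the_outlier_group(self, rng):
        jitter = 1e-3 * rng.standard_normal(9)
        res = anova_tukey({
            "a": np.zeros(3) + jitter[:3],
            "b": np.zeros(3) + jitter[3:6],
            "c": np.full(3, 5.0) + jitter[6:],
        })
        assert res.table["significant"][0]
        tk = res.extra["tukey"]
        flagged = tk[tk["reject"] == True]  # noqa: E712
        pairs = {tuple(sorted((r["group1"], r["group2"]))) for _, r in flagged.iterrows()}
        assert pairs == {("a", "c"), ("b", "c")}

    def test_f_matches_direct_formula(self, rng):
        groups = {g: rng.normal(g, 1.0, 8) for g in range(3)}
        res = anova_tukey(groups)
        # independent one-way ANOVA from sums of squares
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ss_between = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ss_within = sum(((v - np.mean(v)) ** 2).sum() for v in groups.values())
        f = (ss_between / 2) / (ss_within / (len(allv) - 3))
        assert res.table["statistic"][0] == pytest.approx(f, abs=1e-10)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(StatsError, match="2 groups"):
            anova_tukey({3: [1, 2]})


class TestKsCompare:
    def test_identical_pools(self, rng):
        ds = make_dataset(rng.standard_normal((10, 60)))
        res = ks_compare([ds], [ds])
        assert res.table["statistic"][0] == 0.0
        assert res.table["p"][0] == pytest.approx(1.0)

    def test_disjoint_supports_give_d_near_one(self, rng):
        from .conftest import net_from_weights
        def net_with(vals):
            n = 46  # 1035 pairs ≥ 1000 samples
            w = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            w[iu] = vals[: iu[0].size]
            w += w.T
            return net_from_weights(w)
        a = net_with(rng.uniform(-1, -1e-6, 2000))
        b = net_with(rng.uniform(1e-6, 1, 2000))
        res = ks_compare([a], [b])
        assert res.table["statistic"][0] == pytest.approx(1.0)
        assert res.table["p"][0] < 1e-10

    def test_d_matches_brute_force_ecdf(self, rng):
        ds_a = make_dataset(rng.standard_normal((15, 100)))
        ds_b = make_dataset(rng.standard_normal((15, 100)) * 1.5
                            + 0.2 * rng.standard_normal((1, 100)))
        res = ks_compare([ds_a], [ds_b])
        d_ref = brute_ks_statistic(pool_edge_weights([ds_a]),
                                   pool_edge_weights([ds_b]))
        assert res.table["statistic"][0] == pytest.approx(d_ref, abs=1e-12)

    def test_pool_sizes_recorded(self, rng):
        a = [make_dataset(rng.standard_normal((6, 50))) for _ in range(2)]
        b = [make_dataset(rng.standard_normal((5, 50)))]
        res = ks_compare(a, b)
        assert res.table["n_a"][0] == 2 * 15  # two larvae × C(6,2) pairs
        assert res.table["n_b"][0] == 10
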