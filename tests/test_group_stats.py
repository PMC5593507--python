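"""Aggregation, printed percentages, non-parametric tests, Hill fits."""

import itertools

import numpy as np
import pytest
from scipy import stats

from trpquant import (
    average_trace,
    compare_groups,
    compare_multi,
    densitometry_normalize,
    fit_hill,
    percentage,
    significance_stars,
    size_histogram,
)

from .conftest import make_trace


class TestAverageTrace:
    def test_identical_traces(self):
        traces = [make_trace(np.full(10, 1.3)) for _ in range(4)]
        s = average_trace(traces)
        assert np.allclose(s.mean, 1.3)
        assert np.allclose(s.sem, 0.0)

    def test_two_point_closed_form(self):
        traces = [make_trace([0.0, 0.0]), make_trace([2.0, 2.0])]
        s = average_trace(traces)
        # SD of {0, 2} with ddof=1 is sqrt(2); SEM = sqrt(2)/sqrt(2) = 1
        assert np.allclose(s.mean, 1.0)
        assert np.allclose(s.sem, 1.0)

    def test_matches_brute_force(self, rng):
        data = rng.normal(size=(7, 30))
        traces = [make_trace(row) for row in data]
        s = average_trace(traces)
        assert np.allclose(s.mean, data.mean(axis=0))
        assert np.allclose(s.sem, data.std(axis=0, ddof=1) / np.sqrt(7))

    def test_single_trace_sem_missing(self):
        s = average_trace([make_trace(np.ones(5))])
        assert np.all(np.isnan(s.sem))


class TestPercentage:
    def test_half_away_from_zero_rounding(self):
        assert percentage(1, 8, 1) == 12.5
        assert percentage(5, 8, 0) == 63.0  # 62.5 rounds away from zero
        assert percentage(0, 100, 1) == 0.0

    @pytest.mark.parametrize(
        "count,total,decimals,expected",
        [
            (562, 614, 1, 91.5),
            (614, 3576, 0, 17.0),
            (465, 562, 0, 83.0),
            (14, 52, 0, 27.0),
            (14, 614, 0, 2.0),
            (26, 614, 1, 4.2),
        ],
    )
    def test_reported_count_pairs(self, count, total, decimals, expected):
        assert percentage(count, total, decimals) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            percentage(0, 0)


class TestSizeHistogram:
    def test_direct_binning(self):
        table, frac = size_histogram([10.0, 11.0, 12.0])
        counts = dict(zip(table["bin_left_um"], table["count"]))
        assert counts[10.0] == 2  # [10, 12)
        assert counts[12.0] == 1  # [12, 14)
        assert frac == 0.0

    def test_bins_are_half_open(self):
        table, _ = size_histogram([2.0, 3.999999, 4.0])
        counts = dict(zip(table["bin_left_um"], table["count"]))
        assert counts[2.0] == 2
        assert counts[4.0] == 1

    def test_cutoff_strictly_greater(self):
        _, frac = size_histogram([31.0, 31.1, 10.0], cutoff_um=31.0)
        assert frac == pytest.approx(1 / 3)

    def test_matches_counting_oracle(self, rng):
        d = rng.uniform(5, 45, 200)
        table, frac = size_histogram(d)
        for _, row in table.iterrows():
            expected = np.sum((d >= row["bin_left_um"]) & (d < row["bin_right_um"]))
            assert row["count"] == expected
        assert frac == pytest.approx(np.mean(d > 31.0))


def mannwhitney_oracle(a, b):
    """Exact two-sided p by enumerating all group-A rank placements."""
    n, m = len(a), len(b)
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = []
    for pos in itertools.combinations(range(n + m), n):
        r = np.asarray(pos) + 1.0
        us.append(r.sum() - n * (n + 1) / 2)
    us = np.asarray(us)
    return min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))


def wilcoxon_oracle(a, b):
    """Exact two-sided p by enumerating all 2^n sign assignments."""
    d = a - b
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        ws.append((ranks * np.asarray(signs)).sum())
    ws = np.asarray(ws)
    return min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))


class TestCompareGroups:
    def test_identical_groups_nonsignificant(self, rng):
        a = rng.normal(size=10)
        res = compare_groups(a, a + 1e-9)
        assert res.pvalue > 0.5
        assert res.stars == "ns"

    def test_fully_separated_groups_minimal_u(self):
        a = np.arange(10, dtype=float)
        b = a + 100.0
        res = compare_groups(a, b)
        # minimal attainable U for n=m=10 and the exact two-sided p
        assert min(res.statistic, 100 - res.statistic) == 0.0
        assert res.pvalue < 0.001
        assert res.stars == "***"

    def test_star_cutpoints(self):
        assert significance_stars(0.02) == "*"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.01) == "*"  # bands are closed below
        assert significance_stars(0.001) == "**"
        assert significance_stars(0.05) == "ns"

    def test_mannwhitney_matches_enumeration_for_small_n(self, rng):
        for n, m in [(4, 5), (6, 6), (8, 7), (3, 8)]:
            a = rng.normal(0, 1, n)
            b = rng.normal(0.7, 1, m)
            res = compare_groups(a, b)
            assert res.pvalue == pytest.approx(mannwhitney_oracle(a, b))

    def test_wilcoxon_matches_enumeration_for_small_n(self, rng):
        for n in (5, 6, 8):
            a = rng.normal(0, 1, n)
            b = a + rng.normal(0.5, 1, n)
            res = compare_groups(a, b, paired=True)
            assert res.pvalue == pytest.approx(wilcoxon_oracle(a, b))

    def test_all_tied_flagged(self):
        res = compare_groups([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert any("tied" in f for f in res.flags)

    def test_small_sample_flagged(self):
        res = compare_groups([1.0, 2.0], [3.0, 4.0, 5.0])
        assert any("n < 3" in f for f in res.flags)


class TestCompareMulti:
    def test_three_identical_groups_nonsignificant(self, rng):
        g = rng.normal(size=15)
        res = compare_multi([g, np.roll(g, 3), np.roll(g, 7)])
        assert res.omnibus_pvalue > 0.05

    def test_shifted_group_flagged_in_posthoc(self, rng):
        groups = [
            rng.normal(0, 1, 60),
            rng.normal(0, 1, 60),
            rng.normal(2.5, 1, 60),
        ]
        res = compare_multi(groups)
        assert res.omnibus_pvalue < 0.001
        pw = res.pairwise.set_index(["group_i", "group_j"])
        assert pw.loc[(0, 2), "p_adjusted"] < 0.01
        assert pw.loc[(1, 2), "p_adjusted"] < 0.01
        assert pw.loc[(0, 1), "p_adjusted"] > 0.05

    def test_repeated_measures_friedman(self, rng):
        base = rng.normal(0, 1, 25)
        groups = [base, base + rng.normal(0, 0.3, 25), base + 2.0]
        res = compare_multi(groups, repeated=True)
        assert res.test == "friedman+dunn"
        assert res.omnibus_pvalue < 0.01
        pw = res.pairwise.set_index(["group_i", "group_j"])
        assert pw.loc[(0, 2), "p_adjusted"] < 0.05

    def test_two_groups_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 3"):
            compare_multi([rng.normal(size=5), rng.normal(size=5)])

    def test_unequal_blocks_rejected_for_friedman(self, rng):
        with pytest.raises(ValueError, match="equal length"):
            compare_multi(
                [rng.normal(size=5), rng.normal(size=6), rng.normal(size=5)],
                repeated=True,
            )


class TestHillFit:
    @staticmethod
    def hill(d, bottom, top, ic50, h):
        return bottom + (top - bottom) / (1 + (ic50 / d) ** h)

    def test_exact_model_recovery(self):
        doses = np.array([1, 3, 10, 30, 100, 300, 1000, 3000], float)
        r = self.hill(doses, 0.0, 90.0, 100.0, 1.0)
        fit = fit_hill(doses, r)
        assert fit.converged
        assert fit.ic50 == pytest.approx(100.0, rel=0.01)
        assert fit.hill_slope == pytest.approx(1.0, rel=0.01)

    def test_noisy_recovery_within_20_percent(self, rng):
        doses = np.array([1, 3, 10, 30, 100, 300, 1000, 3000], float)
        clean = self.hill(doses, 0.0, 90.0, 100.0, 1.2)
        noisy = clean + rng.normal(0, 0.05 * 90.0, len(doses))
        fit = fit_hill(doses, np.clip(noisy, 0, 100))
        assert abs(fit.ic50 - 100.0) / 100.0 < 0.2

    def test_direction_guard_flags_contradicting_trend(self):
        doses = np.array([1.0, 10.0, 100.0, 1000.0])
        increasing = np.array([5.0, 30.0, 60.0, 90.0])
        fit = fit_hill(doses, increasing, direction="decreasing")
        assert any("direction-mismatch" in f for f in fit.flags)

    def test_voltage_independence_same_ic50_for_scaled_data(self):
        """Identically scaled responses at two potentials give one IC50."""
        doses = np.array([1, 3, 10, 30, 100, 300, 1000, 3000], float)
        r = self.hill(doses, 0.0, 85.0, 50.0, 1.0)
        fit_pos = fit_hill(doses, r)
        fit_neg = fit_hill(doses, r.copy())
        assert fit_pos.ic50 == pytest.approx(fit_neg.ic50, rel=1e-6)

    def test_too_few_distinct_doses_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_hill([1.0, 1.0, 10.0, 10.0], [1.0, 2.0, 3.0, 4.0])


class TestDensitometry:
    def test_identity_and_null(self):
        assert densitometry_normalize(5.0, 5.0) == 1.0
        assert densitometry_normalize(0.0, 3.0) == 0.0

    def test_random_pairs_equal_division(self, rng):
        for _ in range(20):
            ip, lys = rng.uniform(0.1, 10, 2)
            assert densitometry_normalize(ip, lys) == pytest.approx(ip / lys)

    def test_zero_lysate_rejected(self):
        with pytest.raises(ValueError):
            densitometry_normalize(1.0, 0.0)
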