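import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hotcomp.ratemap import (
    PopulationMeta,
    RateMap,
    RateTrace,
    bonferroni_cutoff,
    compare_rates,
    confound_regression,
    plan_windows,
    r_to_rho,
    rho_to_r,
    stitch_windows,
    summarize_ratemap,
    trace_uncertainty,
    wilcoxon_rank_sum,
)


class TestPlanWindows:
    def test_single_window(self):
        plan = plan_windows(2000)
        assert plan.windows == [(1, 2000)]

    def test_two_windows(self):
        plan = plan_windows(3500)
        assert plan.windows == [(1, 2000), (1501, 3500)]

    def test_example_chromosome(self):
        # 10,750 SNPs: regular starts every 1500, final window = last 2000
        plan = plan_windows(10_750)
        assert [w[0] for w in plan.windows] == [
            1, 1501, 3001, 4501, 6001, 7501, 8751,
        ]
        assert len(plan.windows) == 7
        overlaps = [
            a_end - b_start + 1
            for (_, a_end), (b_start, _) in zip(plan.windows, plan.windows[1:])
        ]
        assert overlaps[-1] == 750
        assert all(o >= 500 for o in overlaps)

    @given(n=st.integers(min_value=2, max_value=60_000))
    @settings(max_examples=200, deadline=None)
    def test_plan_properties(self, n):
        plan = plan_windows(n)
        windows = plan.windows
        assert windows[0][0] == 1
        assert windows[-1][1] == n
        # coverage and minimum overlap
        for (s1, e1), (s2, e2) in zip(windows, windows[1:]):
            assert s2 > s1 and e2 > e1
            assert e1 - s2 + 1 >= 500
        if n > 2000:
            assert all(e - s + 1 == 2000 for s, e in windows)
            assert windows[-1] == (n - 1999, n)

    @given(n=st.integers(min_value=2, max_value=60_000))
    @settings(max_examples=100, deadline=None)
    def test_contributions_partition(self, n):
        plan = plan_windows(n)
        ranges = plan.contributions()
        assert ranges[0][0] == 1
        assert ranges[-1][1] == n - 1
        for (_, h1), (l2, _) in zip(ranges, ranges[1:]):
            assert l2 == h1 + 1
        for (ws, we), (lo, hi) in zip(plan.windows, ranges):
            assert ws <= lo <= hi <= we - 1


class TestStitch:
    def test_two_window_boundary(self):
        # windows [1,2000] and [1501,3500]: the first contributes intervals
        # 1..1750, the second 1751..3499
        plan = plan_windows(3500)
        w1 = np.full(1999, 1.0)
        w2 = np.full(1999, 2.0)
        out = stitch_windows([w1, w2], plan)
        assert out.size == 3499
        assert np.all(out[:1750] == 1.0)
        assert np.all(out[1750:] == 2.0)

    def test_single_window_identity(self):
        plan = plan_windows(1500)
        rates = np.arange(1499, dtype=float)
        np.testing.assert_array_equal(stitch_windows([rates], plan), rates)

    def test_index_arithmetic_oracle(self):
        # each interval's stitched value comes from the planned source window
        rng = np.random.default_rng(3)
        n = 10_750
        plan = plan_windows(n)
        per_window = [
            rng.gamma(1.0, 1.0, size=e - s) for s, e in plan.windows
        ]
        out = stitch_windows(per_window, plan)
        assert out.size == n - 1
        for (ws, _we), (lo, hi), rates in zip(
            plan.windows, plan.contributions(), per_window
        ):
            np.testing.assert_array_equal(
                out[lo - 1 : hi], rates[lo - ws : hi - ws + 1]
            )

    def test_mismatch_rejected(self):
        plan = plan_windows(3500)
        with pytest.raises(ValueError, match="expects"):
            stitch_windows([np.ones(10), np.ones(1999)], plan)

    @given(n=st.integers(min_value=2, max_value=30_000))
    @settings(max_examples=50, deadline=None)
    def test_partition_property(self, n):
        plan = plan_windows(n)
        per_window = [np.ones(e - s) for s, e in plan.windows]
        assert stitch_windows(per_window, plan).size == n - 1


class TestRhoToR:
    # reference (rho, Ne) -> r conversions for known population values
    @pytest.mark.parametrize(
        "rho,ne,expected",
        [
            (1.58e-3, 15_744, 2.51),
            (8.66e-3, 4_651, 46.5),
            (0.0, 1000, 0.0),
        ],
    )
    def test_values(self, rho, ne, expected):
        r = rho_to_r(rho, ne)
        assert float(f"{r:.3g}") == pytest.approx(expected)

    def test_invalid_ne(self):
        with pytest.raises(ValueError):
            rho_to_r(1e-3, 0)

    @given(
        rho=st.floats(min_value=0, max_value=1, allow_nan=False),
        ne=st.floats(min_value=1, max_value=1e6),
    )
    @settings(max_examples=100, deadline=None)
    def test_linear_and_invertible(self, rho, ne):
        r = rho_to_r(rho, ne)
        assert r >= 0
        assert r_to_rho(r, ne) == pytest.approx(rho, rel=1e-12, abs=1e-300)
        assert rho_to_r(2 * rho, ne) == pytest.approx(2 * r, rel=1e-12)


class TestSummarize:
    def _meta(self, ne=25_000.0):
        return {"pop": PopulationMeta("pop", ne, 0.1, 10)}

    def test_constant_map(self):
        rmap = RateMap("chr1", [0, 100, 200, 300], [1e-3] * 3, "pop")
        table = summarize_ratemap({"pop": [rmap]}, self._meta(), seed=0)
        c = rho_to_r(1e-3, 25_000.0)
        assert table.loc["pop", "mean_r"] == pytest.approx(c)
        assert table.loc["pop", "median_r"] == pytest.approx(c)
        assert table.loc["pop", "ci_low"] == pytest.approx(c)
        assert table.loc["pop", "ci_high"] == pytest.approx(c)

    def test_spiky_map_mean_exceeds_median(self):
        rng = np.random.default_rng(0)
        rates = rng.gamma(0.3, 1e-3, size=500)  # heavy right tail
        positions = np.arange(501) * 100
        rmap = RateMap("chr1", positions, rates, "pop")
        table = summarize_ratemap({"pop": [rmap]}, self._meta(), seed=0)
        assert table.loc["pop", "mean_r"] > table.loc["pop", "median_r"]

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError, match="no rate maps"):
            summarize_ratemap({"pop": []}, self._meta())

    def test_bootstrap_ci_coverage(self):
        # ~95% of iid-gamma maps should cover the true mean r (200 reps)
        ne = 25_000.0
        true_mean_r = rho_to_r(2.0 * 5e-4, ne)  # gamma(2, 5e-4) mean
        meta = self._meta(ne)
        rng = np.random.default_rng(42)
        hits = 0
        reps = 200
        for _ in range(reps):
            rates = rng.gamma(2.0, 5e-4, size=400)
            rmap = RateMap("chr1", np.arange(401) * 50, rates, "pop")
            t = summarize_ratemap(
                {"pop": [rmap]}, meta, n_boot=400,
                seed=int(rng.integers(2**31)),
            )
            if t.loc["pop", "ci_low"] <= true_mean_r <= t.loc["pop", "ci_high"]:
                hits += 1
        assert 0.89 <= hits / reps <= 0.995


class TestTraceUncertainty:
    def test_constant_trace_zero_width(self):
        rmap = RateMap("chr1", [0, 100, 200], [1e-3, 1e-3], "pop")
        trace = RateTrace(np.full((2, 50), 1e-3))
        res = trace_uncertainty([trace], [rmap])
        assert res.median_cri_width == pytest.approx(0.0)

    def test_normal_trace_width(self):
        # N(est, sigma^2) trace: CrI width ~= 3.92 sigma (+-5%)
        rng = np.random.default_rng(1)
        est, sigma = 5.0, 0.25
        samples = rng.normal(est, sigma, size=(3, 10_000))
        trace = RateTrace(np.clip(samples, 0, None))
        rmap = RateMap("chr1", [0, 10, 20, 30], [est] * 3, "pop")
        res = trace_uncertainty([trace], [rmap])
        assert res.median_cri_width == pytest.approx(3.92 * sigma, rel=0.05)

    def test_narrow_trace_wide_landscape_ratio(self):
        rng = np.random.default_rng(2)
        rates = rng.lognormal(-7, 1.5, size=200)
        positions = np.arange(201) * 100
        rmap = RateMap("chr1", positions, rates, "pop")
        samples = rates[:, None] * (1 + 0.001 * rng.standard_normal((200, 50)))
        res = trace_uncertainty([RateTrace(np.abs(samples))], [rmap])
        assert res.width_ratio > 10

    def test_few_samples_warns(self):
        rmap = RateMap("chr1", [0, 100, 200], [1e-3, 2e-3], "pop")
        trace = RateTrace(np.ones((2, 10)))
        with pytest.warns(UserWarning, match="trace samples"):
            trace_uncertainty([trace], [rmap])


def _oracle_rank_sum_p(x, y):
    """Independent oracle: two-sided p from the U statistic computed by
    pairwise comparisons, enumerating all label assignments."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)

    def u_stat(idx):
        a = pooled[list(idx)]
        b = np.delete(pooled, list(idx))
        wins = sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b)
        return wins

    u_obs = u_stat(range(n))
    mu = n * m / 2.0
    hits = total = 0
    for combo in itertools.combinations(range(n + m), n):
        if abs(u_stat(combo) - mu) >= abs(u_obs - mu) - 1e-9:
            hits += 1
        total += 1
    return hits / total


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_separated_samples(self):
        # exhaustive: 2 of the 20 assignments are as extreme
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_pairwise_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 8, size=2)
        # integer draws force ties
        x = rng.integers(0, 5, size=n).astype(float)
        y = rng.integers(0, 5, size=m).astype(float)
        assert wilcoxon_rank_sum(x, y) == pytest.approx(
            _oracle_rank_sum_p(x, y)
        )

    def test_large_sample_asymptotic(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        y = rng.normal(1, 1, 200)
        p = wilcoxon_rank_sum(x, y)
        assert p < 1e-10


class TestCompareRates:
    def test_bonferroni_cutoff(self):
        assert round(bonferroni_cutoff(45, 0.05), 4) == 0.0011

    def test_basic(self):
        rng = np.random.default_rng(0)
        values = {
            "A": rng.normal(0, 1, 50),
            "B": rng.normal(0, 1, 50),
            "C": rng.normal(5, 1, 50),
        }
        res = compare_rates(values)
        assert res.n_comparisons == 3
        assert res.kruskal_p < 1e-6
        assert res.pairwise_p.loc["A", "C"] < 1e-6
        assert res.pairwise_p.loc["A", "B"] > 0.01
        assert res.pairwise_p.loc["A", "B"] == res.pairwise_p.loc["B", "A"]

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_rates({"A": [1.0], "B": [1.0, 2.0]})


class TestConfoundRegression:
    def test_exact_line(self):
        x = np.array([1.0, 2, 3, 4, 5])
        res = confound_regression(2 * x + 1, x)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.slope_p < 1e-10

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            confound_regression([1.0, 2, 3], [5.0, 5, 5])

    def test_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        res = confound_regression(y, x)
        X = np.column_stack([np.ones(10), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.intercept == pytest.approx(beta[0])
        assert res.slope == pytest.approx(beta[1])
        # statsmodels as an independent p-value oracle
        import statsmodels.api as sm

        fit = sm.OLS(y, X).fit()
        assert res.slope_p == pytest.approx(fit.pvalues[1], rel=1e-8)

    def test_null_calibration(self):
        # independent x, y: p ~ Uniform(0,1), type-I error ~ 0.05
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(200):
            ps.append(
                confound_regression(rng.normal(size=10), rng.normal(size=10)).slope_p
            )
        ps = np.array(ps)
        assert stats.kstest(ps, "uniform").pvalue > 0.001
        assert 0.004 <= np.mean(ps < 0.05) <= 0.096
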