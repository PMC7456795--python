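"""Statistics against hand computations and full-enumeration oracles."""

import itertools
import math

import numpy as np
import pytest

from seegqa.agreement import (
    bland_altman,
    box_cox,
    correlation_regression,
    dagostino_pearson,
    mann_whitney_u,
    wilcoxon_signed_rank,
)


class TestBoxCox:
    def test_formula_values(self):
        fit = box_cox(np.array([3.0, 3.0, 3.0, 3.0]), lam=2.0)
        assert fit.transformed[0] == pytest.approx((9 - 1) / 2)
        fit = box_cox(np.array([math.e] * 4), lam=0.0)
        assert fit.transformed[0] == pytest.approx(1.0)

    def test_lambda_to_zero_limit_is_log(self):
        x = np.array([0.5, 1.0, 2.0, 5.0])
        near = box_cox(x, lam=1e-8).transformed
        assert np.max(np.abs(near - np.log(x))) < 1e-6

    def test_shift_applied_to_nonpositive(self):
        fit = box_cox(np.array([-1.0, 0.0, 1.0, 2.0]))
        assert fit.shift == pytest.approx(1.0 + 1e-6)
        with pytest.raises(ValueError):
            box_cox(np.array([-1.0, 0.0, 1.0, 2.0]), shift=False)

    def test_mle_concentrates(self):
        rng = np.random.default_rng(42)
        lognormal = np.exp(rng.normal(size=500))
        assert abs(box_cox(lognormal).lam - 0.0) < 0.35
        # location chosen so lambda is identifiable (for data whose spread
        # is tiny relative to the mean, the power family is nearly flat)
        normal = rng.normal(loc=3.0, scale=1.0, size=500)
        assert abs(box_cox(normal).lam - 1.0) < 0.35

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            box_cox([1.0, 2.0, 3.0])


def _dagostino_oracle(x):
    """K^2 from the published skewness/kurtosis z-transformations,
    implemented independently from first principles."""
    x = np.asarray(x, float)
    n = x.size
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    m3 = np.mean((x - m) ** 3)
    m4 = np.mean((x - m) ** 4)
    # skewness transform (D'Agostino 1970)
    g1 = m3 / m2**1.5
    Y = g1 * math.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = 3.0 * (n**2 + 27 * n - 70) * (n + 1) * (n + 3) / ((n - 2) * (n + 5) * (n + 7) * (n + 9))
    W2 = -1 + math.sqrt(2 * (beta2 - 1))
    delta = 1 / math.sqrt(0.5 * math.log(W2))
    alpha = math.sqrt(2.0 / (W2 - 1))
    z1 = delta * math.log(Y / alpha + math.sqrt((Y / alpha) ** 2 + 1))
    # kurtosis transform (Anscombe & Glynn 1983)
    g2 = m4 / m2**2
    E = 3.0 * (n - 1) / (n + 1)
    var = 24.0 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    xk = (g2 - E) / math.sqrt(var)
    sb1 = 6.0 * (n**2 - 5 * n + 2) / ((n + 7) * (n + 9)) * math.sqrt(
        6.0 * (n + 3) * (n + 5) / (n * (n - 2) * (n - 3))
    )
    A = 6.0 + 8.0 / sb1 * (2.0 / sb1 + math.sqrt(1 + 4.0 / sb1**2))
    z2 = ((1 - 2.0 / (9 * A)) - ((1 - 2.0 / A) / (1 + xk * math.sqrt(2.0 / (A - 4)))) ** (1 / 3)) / math.sqrt(
        2.0 / (9 * A)
    )
    return z1**2 + z2**2, z1


class TestDagostinoPearson:
    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            dagostino_pearson(np.arange(5.0))

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            dagostino_pearson(np.full(30, 2.0))

    def test_matches_independent_formula_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            x = rng.normal(size=100) + rng.exponential(size=100)
            k2_oracle, _ = _dagostino_oracle(x)
            res = dagostino_pearson(x)
            assert res.statistic == pytest.approx(k2_oracle, abs=1e-8)
            assert res.n == 100

    def test_symmetric_sample_zero_skew_term(self):
        base = np.array([0.3, 0.7, 1.1, 1.9, 2.6, 3.4, 4.1, 4.9, 5.8, 6.6])
        x = np.concatenate([base, -base])
        _, z1 = _dagostino_oracle(x)
        assert z1 == pytest.approx(0.0, abs=1e-12)
        res = dagostino_pearson(x)  # runs without error; K2 = kurtosis term only
        k2, _ = _dagostino_oracle(x)
        assert res.statistic == pytest.approx(k2, abs=1e-8)


class TestBlandAltman:
    def test_hand_computed_three_points(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.1, 2.0, 2.9])
        assert res.bias == pytest.approx(0.0, abs=1e-12)
        assert res.sd == pytest.approx(0.1, abs=1e-12)
        assert res.loa_low == pytest.approx(-0.196, abs=1e-12)
        assert res.loa_high == pytest.approx(0.196, abs=1e-12)

    def test_identical_inputs(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == res.sd == res.loa_low == res.loa_high == 0.0

    def test_ci_contains_point_estimates(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=30)
        b = a + rng.normal(scale=0.5, size=30)
        res = bland_altman(a, b)
        assert res.ci_bias[0] < res.bias < res.ci_bias[1]
        assert res.ci_loa_low[0] < res.loa_low < res.ci_loa_low[1]
        assert res.ci_loa_high[0] < res.loa_high < res.ci_loa_high[1]
        assert res.loa_low <= res.bias <= res.loa_high

    def test_antisymmetric_in_arguments(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=20), rng.normal(size=20)
        r1, r2 = bland_altman(a, b), bland_altman(b, a)
        assert r1.bias == pytest.approx(-r2.bias)
        assert r1.loa_low == pytest.approx(-r2.loa_high)
        assert r1.loa_high == pytest.approx(-r2.loa_low)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0, 3.0], [1.0, 2.0])


def _wilcoxon_enumeration_p(d):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(d, float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_plus_obs = ranks[d > 0].sum()
    n = d.size
    total = n * (n + 1) / 2.0
    stat_obs = min(w_plus_obs, total - w_plus_obs)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w_plus = sum(r for r, s in zip(ranks, signs) if s)
        if min(w_plus, total - w_plus) <= stat_obs + 1e-12:
            count += 1
    return count / 2.0**n


class TestWilcoxonSignedRank:
    def test_all_positive_three(self):
        res = wilcoxon_signed_rank([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.25, abs=1e-12)

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_zero_differences_discarded(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 5.0], [1.0, 1.0, 1.0, 1.0])
        assert res.n == 3  # the zero pair is dropped

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7, 8])
    def test_matches_full_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(20):
            d = rng.normal(size=n) * 3
            while np.unique(np.abs(d)).size < n or np.any(d == 0):
                d = rng.normal(size=n) * 3
            res = wilcoxon_signed_rank(d, np.zeros(n))
            assert res.p_value == pytest.approx(_wilcoxon_enumeration_p(d), abs=1e-12)

    def test_null_mean_statistic_p_near_one(self):
        res = wilcoxon_signed_rank([-2.0, -1.0, 1.0, 2.0], [0.0] * 4)
        assert res.p_value > 0.9

    def test_exact_vs_approx_crossover_agree(self):
        rng = np.random.default_rng(99)
        for _ in range(10):
            d = rng.normal(size=15)
            p_exact = wilcoxon_signed_rank(d, np.zeros(15)).p_value
            from scipy import stats

            p_approx = float(stats.wilcoxon(d, correction=True, method="approx").pvalue)
            assert abs(p_exact - p_approx) < 0.02


def _mannwhitney_enumeration_p(x, y):
    """Exact two-sided p by enumerating all C(n+m, n) group assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2.0
    u_mirror = nx * ny - u_obs
    tail = min(u_obs, u_mirror)
    count = 0
    total = 0
    for combo in itertools.combinations(range(nx + ny), nx):
        total += 1
        u = ranks[list(combo)].sum() - nx * (nx + 1) / 2.0
        if min(u, nx * ny - u) <= tail + 1e-12:
            count += 1
    return count / total


class TestMannWhitneyU:
    def test_complete_separation_small(self):
        res = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_multisets_half_u(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(4.5)  # n_x n_y / 2

    def test_single_elements(self):
        res = mann_whitney_u([1.0], [2.0])
        assert res.statistic == 0.0

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize("nx,ny", [(2, 2), (3, 3), (3, 5), (4, 4), (2, 6)])
    def test_matches_full_enumeration(self, nx, ny):
        rng = np.random.default_rng(nx * 10 + ny)
        for _ in range(15):
            pooled = rng.normal(size=nx + ny) * 2
            while np.unique(pooled).size < nx + ny:
                pooled = rng.normal(size=nx + ny) * 2
            x, y = pooled[:nx], pooled[nx:]
            res = mann_whitney_u(x, y)
            assert res.p_value == pytest.approx(_mannwhitney_enumeration_p(x, y), abs=1e-12)

    def test_exact_vs_approx_crossover_agree(self):
        rng = np.random.default_rng(13)
        from scipy import stats

        for _ in range(10):
            x, y = rng.normal(size=6), rng.normal(size=6)
            p_exact = mann_whitney_u(x, y).p_value
            p_approx = float(stats.mannwhitneyu(x, y, method="asymptotic").pvalue)
            assert abs(p_exact - p_approx) < 0.02


class TestCorrelationRegression:
    def test_exact_linear(self):
        x = np.arange(1.0, 11.0)
        rho, slope, intercept = correlation_regression(x, 2 * x + 1)
        assert rho == pytest.approx(1.0)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)

    def test_anticorrelated(self):
        x = np.arange(1.0, 8.0)
        rho, slope, _ = correlation_regression(x, -x)
        assert rho == pytest.approx(-1.0)
        assert slope == pytest.approx(-1.0)

    def test_matches_sigma_formula_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=40)
        y = 1.5 * x + rng.normal(scale=0.5, size=40)
        rho, slope, intercept = correlation_regression(x, y)
        n = x.size
        sxy = np.sum(x * y) - np.sum(x) * np.sum(y) / n
        sxx = np.sum(x * x) - np.sum(x) ** 2 / n
        syy = np.sum(y * y) - np.sum(y) ** 2 / n
        assert rho == pytest.approx(sxy / math.sqrt(sxx * syy), abs=1e-10)
        assert slope == pytest.approx(sxy / sxx, abs=1e-10)
        assert intercept == pytest.approx(np.mean(y) - sxy / sxx * np.mean(x), abs=1e-10)

    def test_constant_x_error(self):
        with pytest.raises(ValueError):
            correlation_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
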