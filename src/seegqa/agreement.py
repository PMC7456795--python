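"""Method-agreement and comparison statistics.

The validation toolbox for comparing two ways of measuring the same
electrodes (e.g. bolt-axis vs. line-of-best-fit metrics, scalp vs. skull
entry surfaces): Box-Cox normalization, D'Agostino-Pearson normality,
Bland-Altman agreement with ±1.96σ limits and their confidence intervals,
Wilcoxon signed-rank and Mann-Whitney U tests, and Pearson correlation with
ordinary least-squares regression.

Bland-Altman is implemented here directly (bias, limits and the classical
CI approximation var(limit) ≈ 3σ²/n); the rank tests and normality test
delegate to SciPy, with exact small-sample p-values cross-checked against
full enumeration in the test suite.  All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BlandAltmanResult",
    "BoxCoxFit",
    "TestResult",
    "bland_altman",
    "box_cox",
    "correlation_regression",
    "dagostino_pearson",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
]


@dataclass(frozen=True)
class TestResult:
    """A named test statistic with its two-sided p-value and sample sizes."""

    name: str
    statistic: float
    p_value: float
    n: int
    n2: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class BoxCoxFit:
    """Box-Cox power transform y = (x^λ − 1)/λ (ln x at λ = 0).

    ``shift`` is the offset added to enforce positivity (0 when the data
    are already positive); ``transformed`` are the transformed values.
    """

    lam: float
    shift: float
    transformed: np.ndarray


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement between two paired measurement methods.

    ``bias`` is the mean of the differences a − b, ``sd`` their sample
    standard deviation, and the limits of agreement are bias ± 1.96·sd —
    the interval expected to contain 95% of individual differences.
    """

    n: int
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    ci_bias: tuple[float, float]
    ci_loa_low: tuple[float, float]
    ci_loa_high: tuple[float, float]


def box_cox(x, lam: float | None = None, shift: bool = True) -> BoxCoxFit:
    """Box-Cox transform; λ is estimated by profile maximum likelihood over
    [−5, 5] when not given.

    Nonpositive inputs are shifted by −min + 1e-6 (recorded in the fit)
    unless ``shift=False``, in which case they are an error.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("box_cox needs at least 4 values")
    offset = 0.0
    if x.min() <= 0:
        if not shift:
            raise ValueError("nonpositive values and shifting disabled")
        offset = -float(x.min()) + 1e-6
    xs = x + offset
    if lam is None:
        res = optimize.minimize_scalar(
            lambda l: -stats.boxcox_llf(l, xs), bounds=(-5.0, 5.0), method="bounded"
        )
        lam = float(res.x)
    lam = float(lam)
    if abs(lam) < 1e-12:
        y = np.log(xs)
    else:
        y = (xs**lam - 1.0) / lam
    return BoxCoxFit(lam=lam, shift=offset, transformed=y)


def dagostino_pearson(x) -> TestResult:
    """D'Agostino-Pearson omnibus normality test.

    K² combines the skewness and kurtosis z-transforms and is referred to a
    chi-square with 2 df.  Requires n ≥ 8 (the kurtosis transform is
    undefined below that); a warning-level small-sample regime applies for
    8 ≤ n < 20.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError("dagostino_pearson needs n >= 8")
    if np.ptp(x) == 0:
        raise ValueError("constant sample")
    if x.size < 20:
        import warnings

        warnings.warn("normality test underpowered for n < 20", stacklevel=2)
    k2, p = stats.normaltest(x)
    return TestResult(name="K2", statistic=float(k2), p_value=float(p), n=int(x.size))


def bland_altman(a, b, loa_factor: float = 1.96, ci_level: float = 0.95) -> BlandAltmanResult:
    """Bland-Altman agreement analysis of paired measurements ``a`` and ``b``.

    Differences d = a − b give the bias μ = mean(d), sd σ (n−1 denominator)
    and limits of agreement μ ± ``loa_factor``·σ.  Confidence intervals use
    the t distribution: the bias CI has standard error σ/√n and each limit's
    CI uses the classical approximation se = σ·√(3/n).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 3:
        raise ValueError("bland_altman needs n >= 3")
    d = a - b
    mu = float(d.mean())
    sd = float(d.std(ddof=1))
    lo = mu - loa_factor * sd
    hi = mu + loa_factor * sd
    tcrit = float(stats.t.ppf(0.5 + ci_level / 2.0, n - 1))
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    return BlandAltmanResult(
        n=n,
        bias=mu,
        sd=sd,
        loa_low=lo,
        loa_high=hi,
        ci_bias=(mu - tcrit * se_bias, mu + tcrit * se_bias),
        ci_loa_low=(lo - tcrit * se_loa, lo + tcrit * se_loa),
        ci_loa_high=(hi - tcrit * se_loa, hi + tcrit * se_loa),
    )


#: largest effective n for which the signed-rank p-value is exact
WILCOXON_EXACT_N = 15
#: largest combined n for which the rank-sum p-value is exact (no ties)
MANNWHITNEY_EXACT_N = 12


def wilcoxon_signed_rank(a, b) -> TestResult:
    """Paired Wilcoxon signed-rank test (two-sided).

    Zero differences are discarded (classical treatment); ties share
    average ranks.  W is the smaller of the signed rank sums.  The p-value
    is exact by enumeration for effective n ≤ 15 and a tie/continuity
    corrected normal approximation otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    has_ties = np.unique(np.abs(d)).size < d.size
    if d.size <= WILCOXON_EXACT_N and not has_ties:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=(method == "approx"),
                         alternative="two-sided", method=method)
    return TestResult(name="W", statistic=float(res.statistic), p_value=float(res.pvalue), n=int(d.size))


def mann_whitney_u(x, y) -> TestResult:
    """Mann-Whitney U test for two independent groups (two-sided).

    U is reported for the first group.  Exact p by enumeration when
    n_x + n_y ≤ 12 with no ties, else a tie-corrected normal approximation
    with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= MANNWHITNEY_EXACT_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return TestResult(name="U", statistic=float(res.statistic), p_value=float(res.pvalue),
                      n=int(x.size), n2=int(y.size))


def correlation_regression(x, y):
    """Pearson correlation and OLS regression of y on x.

    Returns ``(rho, slope, intercept)``.  Used to relate lateral-shift and
    Euclidean metrics, whose target-point correlation drops when insertion
    depth errors are present.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("correlation_regression needs paired samples, n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant x")
    lr = stats.linregress(x, y)
    rho = float(stats.pearsonr(x, y).statistic)
    return rho, float(lr.slope), float(lr.intercept)
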