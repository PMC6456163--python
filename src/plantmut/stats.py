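"""Statistical battery for mutation-accumulation analyses.

Small, well-specified tests used throughout the analyses: the
variance/mean dispersion test against a homogeneous-rate null (significance
by simulation), Yates-corrected chi-square in both 2x2 and goodness-of-fit
forms, the Brunner-Munzel rank test for two-sample stochastic equality,
a conditional (binomial) comparison of two Poisson rates, ordinary least
squares with slope and intercept tests, and Spearman rank correlation with
exact small-sample p-values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm


# -- dispersion --------------------------------------------------------------


@dataclass(frozen=True)
class DispersionResult:
    """Dispersion index with its simulated null distribution summary."""

    D: float
    n: int
    reps: int
    mean_sim_D: float
    sd_sim_D: float
    p_value: float
    seed: int | None
    method: str

    def __post_init__(self) -> None:
        if self.D < 0 or not (0.0 <= self.p_value <= 1.0):
            raise ValueError("invalid dispersion result")


def dispersion_index(counts) -> float:
    """Variance/mean of counts (sample variance, ddof=1)."""
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 counts")
    mean = counts.mean()
    if mean == 0:
        raise ValueError("dispersion undefined for zero mean")
    return float(counts.var(ddof=1) / mean)


def dispersion_null(
    n: int,
    total: int | None = None,
    mean: float | None = None,
    reps: int = 10000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    method: str = "conditional",
) -> np.ndarray:
    """Simulated null distribution of the dispersion index D.

    ``method='conditional'`` (default) redistributes the observed total
    count uniformly at random over the n units (multinomial), i.e. it
    conditions on the total — the natural permutation null for "are some
    branches more mutagenic than others given this many mutations".
    ``method='poisson'`` draws n independent Poisson counts with the
    observed mean (the unconditional plug-in null). Both have E[D] ~ 1 and
    sd(D) ~ sqrt(2/(n-1)).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if method == "conditional":
        if total is None:
            if mean is None:
                raise ValueError("conditional null needs total or mean")
            total = int(round(mean * n))
        sims = rng.multinomial(total, [1.0 / n] * n, size=reps)
    elif method == "poisson":
        if mean is None:
            if total is None:
                raise ValueError("poisson null needs mean or total")
            mean = total / n
        sims = rng.poisson(mean, size=(reps, n))
    else:
        raise ValueError(f"unknown method {method!r}")
    means = sims.mean(axis=1)
    ok = means > 0
    return sims[ok].var(axis=1, ddof=1) / means[ok]


def dispersion_test(
    counts,
    reps: int = 10000,
    seed: int | None = None,
    method: str = "conditional",
    rng: np.random.Generator | None = None,
) -> DispersionResult:
    """Test per-branch mutation counts against a homogeneous-rate null.

    D = variance/mean of the observed counts; the p-value is the fraction of
    simulated null datasets whose D is at least the observed one.
    """
    counts = np.asarray(counts, dtype=int)
    D = dispersion_index(counts)
    sims = dispersion_null(
        n=counts.size,
        total=int(counts.sum()),
        mean=float(counts.mean()),
        reps=reps,
        rng=rng,
        seed=seed,
        method=method,
    )
    return DispersionResult(
        D=D,
        n=int(counts.size),
        reps=reps,
        mean_sim_D=float(sims.mean()),
        sd_sim_D=float(sims.std(ddof=1)),
        p_value=float(np.mean(sims >= D)),
        seed=seed,
        method=method,
    )


# -- chi-square with Yates correction ----------------------------------------


def chisq_yates(
    table=None,
    observed=None,
    expected=None,
) -> tuple[float, int, float]:
    """Chi-square with Yates continuity correction.

    Either a 2x2 ``table`` (statistic
    N(|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d)), df = 1) or
    ``observed``/``expected`` vectors (goodness of fit,
    sum((|O - E| - 1/2)^2 / E), df = k - 1). The correction never drives a
    term below zero.
    """
    if table is not None:
        t = np.asarray(table, dtype=float)
        if t.shape != (2, 2) or np.any(t < 0):
            raise ValueError("table must be a nonnegative 2x2 array")
        a, b = t[0]
        c, d = t[1]
        n = t.sum()
        margins = (a + b) * (c + d) * (a + c) * (b + d)
        if margins == 0:
            raise ValueError("degenerate table margin")
        num = max(abs(a * d - b * c) - n / 2.0, 0.0)
        stat = n * num * num / margins
        df = 1
    else:
        if observed is None or expected is None:
            raise ValueError("provide a 2x2 table or observed+expected")
        o = np.asarray(observed, dtype=float)
        e = np.asarray(expected, dtype=float)
        if o.shape != e.shape or np.any(o < 0):
            raise ValueError("observed/expected must match and be nonnegative")
        if np.any(e <= 0):
            raise ValueError("expected counts must be positive")
        stat = float(np.sum(np.maximum(np.abs(o - e) - 0.5, 0.0) ** 2 / e))
        df = o.size - 1
    return float(stat), int(df), float(sps.chi2.sf(stat, df))


# -- Brunner-Munzel ----------------------------------------------------------


@dataclass(frozen=True)
class BrunnerMunzelResult:
    statistic: float
    p_value: float
    estimate: float  # P(X < Y) + 0.5 P(X = Y)
    df: float


def brunner_munzel(x, y) -> BrunnerMunzelResult:
    """Brunner-Munzel test of stochastic equality of two samples.

    Uses midranks of the pooled sample: with mean pooled ranks R1., R2. and
    within-sample rank variances S1^2, S2^2, the statistic is

        W = n1 n2 (R2. - R1.) / ((n1 + n2) sqrt(n1 S1^2 + n2 S2^2))

    referred to a t distribution with Satterthwaite-style degrees of
    freedom. The relative effect p-hat = P(X < Y) + P(X = Y)/2 is reported.
    Fully tied (zero-variance) inputs are degenerate: p = 1, W = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need size >= 2")
    pooled = np.concatenate([x, y])
    r = sps.rankdata(pooled)
    r1, r2 = r[:n1], r[n1:]
    r1m, r2m = r1.mean(), r2.mean()
    estimate = (r2m - (n2 + 1) / 2.0) / n1
    r1_in = sps.rankdata(x)
    r2_in = sps.rankdata(y)
    s1sq = np.sum((r1 - r1_in - r1m + (n1 + 1) / 2.0) ** 2) / (n1 - 1)
    s2sq = np.sum((r2 - r2_in - r2m + (n2 + 1) / 2.0) ** 2) / (n2 - 1)
    denom_sq = n1 * s1sq + n2 * s2sq
    if denom_sq <= 0:
        # degenerate variance: either the samples are fully tied with each
        # other (no evidence of a difference) or completely separated, in
        # which case an exchangeability bound 2/C(n1+n2, n1) replaces the
        # undefined t-approximation
        if estimate in (0.0, 1.0):
            p = min(1.0, 2.0 / math.comb(n1 + n2, n1))
            w = math.inf if estimate == 1.0 else -math.inf
            return BrunnerMunzelResult(w, p, float(estimate), float("nan"))
        return BrunnerMunzelResult(0.0, 1.0, float(estimate), float("nan"))
    w = n1 * n2 * (r2m - r1m) / ((n1 + n2) * math.sqrt(denom_sq))
    df = denom_sq ** 2 / (
        (n1 * s1sq) ** 2 / (n1 - 1) + (n2 * s2sq) ** 2 / (n2 - 1)
    )
    p = 2.0 * sps.t.sf(abs(w), df)
    return BrunnerMunzelResult(float(w), float(min(p, 1.0)), float(estimate), float(df))


# -- Poisson rate comparison -------------------------------------------------


def poisson_rate_comparison(
    c1: int,
    c2: int,
    exposure_ratio: float = 1.0,
    alternative: str = "greater",
) -> float:
    """Conditional comparison of two Poisson rates.

    Under the null (rates equal up to ``exposure_ratio`` = exposure1 /
    exposure2), given the total c1 + c2 the first count is
    Binomial(c1 + c2, exposure_ratio / (1 + exposure_ratio)). The one-sided
    p-value is the binomial tail including the observed count.
    """
    if c1 < 0 or c2 < 0:
        raise ValueError("counts must be nonnegative")
    if exposure_ratio <= 0:
        raise ValueError("exposure_ratio must be positive")
    total = c1 + c2
    if total == 0:
        return 1.0
    p0 = exposure_ratio / (1.0 + exposure_ratio)
    if alternative == "greater":
        return float(sps.binom.sf(c1 - 1, total, p0))
    if alternative == "less":
        return float(sps.binom.cdf(c1, total, p0))
    if alternative == "two-sided":
        return float(sps.binomtest(c1, total, p0).pvalue)
    raise ValueError(f"unknown alternative {alternative!r}")


# -- ordinary least squares --------------------------------------------------


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float
    p_intercept: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared out of range")


def ols_fit(x, y) -> RegressionResult:
    """Least-squares line y = slope*x + intercept with slope and intercept
    t-tests (the intercept test checks departure from zero)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_slope=float(model.pvalues[1]),
        p_intercept=float(model.pvalues[0]),
        n=int(x.size),
    )


# -- Spearman ----------------------------------------------------------------


def spearman(x, y, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rank correlation with exact p for small tie-free samples.

    For n <= ``exact_max_n`` and no ties, the two-sided p-value enumerates
    all n! rank permutations (fraction with |rho| >= |observed|); otherwise
    the usual t approximation applies.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    rho, p_approx = sps.spearmanr(x, y)
    ties = len(set(x)) < n or len(set(y)) < n
    if n <= exact_max_n and not ties:
        rx = sps.rankdata(x)
        count = total = 0
        obs = abs(rho)
        ranks = sps.rankdata(y)
        for perm in itertools.permutations(ranks):
            r = np.corrcoef(rx, perm)[0, 1]
            if abs(r) >= obs - 1e-12:
                count += 1
            total += 1
        return float(rho), count / total
    return float(rho), float(p_approx)
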