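"""Two-sample and goodness-of-fit tests, operable from raw samples or from
published summary triples (mean, SD, n).

All p-values are two-tailed.  The pooled-variance Student t is the default
two-sample test (the degrees of freedom printed alongside the quantities
this package targets, e.g. df = n₁ + n₂ − 2, identify pooled t); a Welch
variant with Satterthwaite degrees of freedom is provided for unequal
variances.  The Mann-Whitney U is reported with the min(U₁, U₂) convention
and an exact enumeration p where feasible.  No multiple-testing correction
is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class SummaryStats:
    """A published (mean, SD, n) triple."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("summary requires n ≥ 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @classmethod
    def from_sample(cls, x) -> "SummaryStats":
        x = np.asarray(x, dtype=float)
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=x.size)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float] | None
    p_two_tailed: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_two_tailed <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"{self.method}: statistic={self.statistic:.4g}, "
                f"df={self.df}, p={self.p_two_tailed:.4g}")


def pooled_t_from_summary(a: SummaryStats, b: SummaryStats) -> TestResult:
    """Student's pooled-variance two-sample t from summary triples.

    The statistic is signed as mean(a) − mean(b); df = n_a + n_b − 2.
    Zero pooled variance with equal means gives t = 0, p = 1; with unequal
    means it is an error.
    """
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2) / df
    diff = a.mean - b.mean
    if sp2 == 0:
        if diff == 0:
            return TestResult(0.0, df, 1.0, "pooled t")
        raise ZeroDivisionError("zero pooled variance with unequal means")
    t = diff / math.sqrt(sp2 * (1 / a.n + 1 / b.n))
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult(t, df, min(p, 1.0), "pooled t")


def welch_t_from_summary(a: SummaryStats, b: SummaryStats) -> TestResult:
    """Welch's unequal-variance t with Satterthwaite degrees of freedom."""
    va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
    diff = a.mean - b.mean
    if va + vb == 0:
        if diff == 0:
            return TestResult(0.0, float(a.n + b.n - 2), 1.0, "Welch t")
        raise ZeroDivisionError("zero variance with unequal means")
    t = diff / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return TestResult(t, df, min(p, 1.0), "Welch t")


def pooled_t(x, y) -> TestResult:
    return pooled_t_from_summary(SummaryStats.from_sample(x),
                                 SummaryStats.from_sample(y))


def welch_t(x, y) -> TestResult:
    return welch_t_from_summary(SummaryStats.from_sample(x),
                                SummaryStats.from_sample(y))


_EXACT_LIMIT = 200_000  # max C(n, n_x) label assignments to enumerate


def _u_statistics(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(U_x, U_y) with midranks for ties."""
    nx, ny = x.size, y.size
    ranks = sps.rankdata(np.concatenate([x, y]))
    ux = float(ranks[:nx].sum() - nx * (nx + 1) / 2)
    return ux, nx * ny - ux


def mann_whitney_u(x, y) -> TestResult:
    """Mann-Whitney U with midranks; statistic = min(U_x, U_y).

    The two-tailed p is exact — enumeration of all C(n, n_x) group labelings
    of the pooled data, which handles ties exactly — whenever that count is
    ≤ 2·10⁵; otherwise the normal approximation with tie correction and a
    0.5 continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    ux, uy = _u_statistics(x, y)
    u = min(ux, uy)
    if math.comb(nx + ny, nx) <= _EXACT_LIMIT:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        offset = nx * (nx + 1) / 2
        us = np.array([ranks[list(idx)].sum() - offset
                       for idx in combinations(range(nx + ny), nx)])
        total = us.size
        # two-tailed: double the smaller tail of the U_x null distribution
        eps = 1e-9
        lo = np.count_nonzero(us <= ux + eps) / total
        hi = np.count_nonzero(us >= ux - eps) / total
        p = min(1.0, 2 * min(lo, hi))
        method = "Mann-Whitney U (exact)"
    else:
        mu = nx * ny / 2
        pooled = np.concatenate([x, y])
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts ** 3 - counts) / ((nx + ny) * (nx + ny - 1))
        sigma2 = nx * ny / 12 * (nx + ny + 1 - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (abs(ux - mu) - 0.5) / math.sqrt(sigma2)
            p = min(1.0, 2 * sps.norm.sf(max(z, 0.0)))
        method = "Mann-Whitney U (normal approx.)"
    return TestResult(u, None, p, method)


def chi_square_gof(observed, expected_proportions) -> TestResult:
    """Goodness-of-fit χ² = Σ(O−E)²/E with df = classes − 1."""
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and expected shapes differ")
    if not math.isclose(props.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("expected proportions must sum to 1")
    exp = props * obs.sum()
    if np.any(exp <= 0):
        raise ValueError("zero expected count")
    stat = float(np.sum((obs - exp) ** 2 / exp))
    df = obs.size - 1
    return TestResult(stat, df, float(sps.chi2.sf(stat, df)), "chi-square GoF")


def f_test_variances(a: SummaryStats, b: SummaryStats) -> TestResult:
    """F-test of equality of variances: F = s_a²/s_b², df (n_a−1, n_b−1).

    Two-tailed p = 2·min(P(F ≥ f), P(F ≤ f)), capped at 1.
    """
    if b.sd == 0:
        raise ZeroDivisionError("zero variance in denominator group")
    f = a.sd ** 2 / b.sd ** 2
    dfa, dfb = a.n - 1, b.n - 1
    p = 2 * min(sps.f.sf(f, dfa, dfb), sps.f.cdf(f, dfa, dfb))
    return TestResult(f, (dfa, dfb), min(p, 1.0), "F test of variances")


def f_test_variances_from_samples(x, y) -> TestResult:
    return f_test_variances(SummaryStats.from_sample(x),
                            SummaryStats.from_sample(y))
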