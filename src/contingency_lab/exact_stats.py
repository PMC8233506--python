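"""Exact and small-sample statistics for contingency analyses.

Implements the Wilson score interval for a binomial proportion, the exact
binomial test, and Fisher's exact test on 2x2 tables.  The binomial and
Fisher tests are built on explicit enumeration of the outcome space with
integer arithmetic where possible, so tail sums are exact up to the final
float conversion.  Two-sided p-values follow the point-probability
convention: sum the probabilities of all outcomes no more probable than the
observed one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import stats as _st

__all__ = [
    "ContingencyTable2x2",
    "wilson_ci",
    "binomial_test",
    "fisher_exact",
    "t_test_means",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table of counts; rows are groups, columns outcome present/absent."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"cells must be non-negative integers, got {cells}")
        if sum(cells) == 0:
            raise ValueError("table is empty: every margin is zero")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def is_degenerate(self) -> bool:
        """True when a whole row or column is zero (no association testable)."""
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        )


def wilson_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion k/n.

    Unlike the Wald interval, the Wilson interval has the nominal coverage
    near the boundaries and always lies inside [0, 1]; its lower bound is
    exactly 0 when k == 0 and its upper bound exactly 1 when k == n.
    """
    if not 0 < conf < 1:
        raise ValueError(f"conf must lie in (0, 1), got {conf}")
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    z = _st.norm.ppf(0.5 + conf / 2.0)
    phat = k / n
    z2n = z * z / n
    denom = 1.0 + z2n
    center = (phat + z2n / 2.0) / denom
    half = z * math.sqrt(phat * (1.0 - phat) / n + z2n / (4.0 * n)) / denom
    low = float(max(0.0, center - half))
    high = float(min(1.0, center + half))
    if k == 0:
        low = 0.0
    if k == n:
        high = 1.0
    return low, high


def binomial_test(k: int, n: int, p0: float, alternative: str = "two-sided") -> float:
    """Exact binomial test of k successes in n trials against null proportion p0.

    The two-sided p-value sums P(X = i) over every outcome i whose point
    probability does not exceed that of the observed k (with a small
    relative tolerance to absorb floating-point ties).
    """
    if not 0 < p0 < 1:
        raise ValueError(f"p0 must lie strictly in (0, 1), got {p0}")
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pmf = _st.binom.pmf(range(n + 1), n, p0)
    if alternative == "less":
        p = pmf[: k + 1].sum()
    elif alternative == "greater":
        p = pmf[k:].sum()
    else:
        p = pmf[pmf <= pmf[k] * (1.0 + 1e-12)].sum()
    return float(min(1.0, p))


def _hypergeom_numerators(r1: int, r2: int, c1: int) -> tuple[range, list[int]]:
    """Integer numerators C(r1, x) * C(r2, c1 - x) over the support of x."""
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    support = range(lo, hi + 1)
    nums = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in support]
    return support, nums


def fisher_exact(table: ContingencyTable2x2, alternative: str = "two-sided") -> float:
    """Fisher's exact test for a 2x2 table by hypergeometric enumeration.

    Conditions on both margins and enumerates every table consistent with
    them.  Because all tables share the denominator C(n, c1), tail sums are
    formed from exact integer numerators; ties in the two-sided sum are
    therefore exact, not float-dependent.

    alternative:
      'greater'  -- enrichment of the top-left cell (a) beyond expectation
      'less'     -- depletion of the top-left cell
      'two-sided' -- sum of all tables with point probability <= observed
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if table.is_degenerate():
        warnings.warn(
            "degenerate table (a zero row or column): no association testable, p = 1",
            UserWarning,
            stacklevel=2,
        )
        return 1.0
    r1, r2 = table.a + table.b, table.c + table.d
    c1 = table.a + table.c
    support, nums = _hypergeom_numerators(r1, r2, c1)
    denom = math.comb(table.total, c1)
    obs = nums[table.a - support.start]
    if alternative == "greater":
        tail = sum(v for x, v in zip(support, nums) if x >= table.a)
    elif alternative == "less":
        tail = sum(v for x, v in zip(support, nums) if x <= table.a)
    else:
        tail = sum(v for v in nums if v <= obs)
    return tail / denom


def t_test_means(x, y, paired: bool = False) -> tuple[float, float]:
    """Convenience two-sample t-test (statistic, p). Thin wrapper, unvalidated."""
    if paired:
        res = _st.ttest_rel(x, y)
    else:
        res = _st.ttest_ind(x, y)
    return float(res.statistic), float(res.pvalue)
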