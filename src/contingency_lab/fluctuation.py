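"""Mutation-rate estimation from fluctuation assays.

A fluctuation assay grows many parallel cultures from small mutant-free
inocula and counts mutant colonies in each.  Because a mutation arising
early in a culture's expansion leaves many descendants ("jackpots"), the
count distribution is the heavy-tailed Luria-Delbruck law rather than
Poisson.  The expected number of mutation *events* per culture, m, is
estimated by maximum likelihood using the Ma-Sandri-Sarkar (MSS) recursion
for the count distribution; the per-cell per-generation rate is then
m / N_tot where N_tot is the total number of cells grown in the culture.

Two corrections mirror the laboratory procedure:

* plating efficiency p_eff (not every mutant plated forms a visible
  colony): counts are multiplied by 1/p_eff *before* estimation
  (:func:`correct_counts`), the same pipeline order as the assay analysis
  this module reproduces.  A likelihood-level alternative exists via the
  thinning machinery but is off by default.
* partial plating (only a volume fraction of each culture is plated):
  handled inside the likelihood by binomial thinning of the MSS
  distribution.

The profile-likelihood 95% CI takes the m values at which the
log-likelihood drops 1.92 units (chi-square, 1 df) below its maximum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FluctuationAssay",
    "PlatingEfficiency",
    "RateEstimate",
    "FluctuationModel",
    "plating_efficiency",
    "correct_counts",
    "estimate_rate",
    "luria_delbruck_pmf",
    "thinned_pmf",
]

# log-likelihood drop defining the 95% profile interval (chi2_{1,0.95}/2)
_PROFILE_DROP = 1.9207


@dataclass(frozen=True)
class FluctuationAssay:
    """Mutant colony counts from parallel cultures.

    counts            mutant colonies per culture
    n_final           viable cells in the plated sample of each culture
    volume_fraction   fraction of each culture that was plated
    """

    counts: tuple[int, ...]
    n_final: float
    volume_fraction: float = 1.0

    def __post_init__(self) -> None:
        if len(self.counts) == 0:
            raise ValueError("assay needs at least one culture")
        if any(c < 0 or int(c) != c for c in self.counts):
            raise ValueError("counts must be non-negative integers")
        if self.n_final < 1:
            raise ValueError(f"n_final must be >= 1, got {self.n_final}")
        if not 0 < self.volume_fraction <= 1:
            raise ValueError(
                f"volume_fraction must lie in (0, 1], got {self.volume_fraction}"
            )
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))

    @property
    def n_total_effective(self) -> float:
        """Cells grown in the whole culture (plated cells / plated fraction)."""
        return self.n_final / self.volume_fraction


@dataclass(frozen=True)
class PlatingEfficiency:
    """Fraction of true mutants forming visible colonies under selection."""

    m_c: int
    m_e: int
    p_eff: float = field(init=False)

    def __post_init__(self) -> None:
        if self.m_e < 1:
            raise ValueError("m_e (permissive-plate colonies) must be >= 1")
        if self.m_c < 0:
            raise ValueError("m_c must be non-negative")
        p = self.m_c / self.m_e
        if p == 0:
            raise ValueError(
                "zero plating efficiency: selective counts cannot be corrected"
            )
        if p > 1:
            warnings.warn(
                f"m_c > m_e ({self.m_c} > {self.m_e}); clamping p_eff to 1",
                UserWarning,
                stacklevel=2,
            )
            p = 1.0
        object.__setattr__(self, "p_eff", p)


def plating_efficiency(m_c: int, m_e: int) -> PlatingEfficiency:
    """p_eff = m_c / m_e from a co-plating calibration."""
    return PlatingEfficiency(m_c=m_c, m_e=m_e)


def correct_counts(counts, p_eff: float) -> list[int]:
    """Scale counts by 1/p_eff, rounding to the nearest integer (ties to even).

    The division is snapped to 9 decimals before rounding so that exact
    halves produced through decimal efficiencies (e.g. 3 / 0.4 = 7.5) round
    by the ties-to-even rule rather than by float representation error.
    """
    if isinstance(p_eff, PlatingEfficiency):
        p_eff = p_eff.p_eff
    if not 0 < p_eff <= 1:
        raise ValueError(f"p_eff must lie in (0, 1], got {p_eff}")
    return [int(round(round(c / p_eff, 9))) for c in counts]


def luria_delbruck_pmf(m: float, nmax: int) -> np.ndarray:
    """P(0..nmax mutant cells) under the Luria-Delbruck law via MSS recursion.

    p_0 = e^-m;  p_n = (m/n) * sum_{i<n} p_i / (n - i + 1).

    Equivalent to a compound Poisson with Poisson(m) mutation events and
    single-clone size distribution P(j) = 1/(j (j+1)).
    """
    if m < 0:
        raise ValueError("m must be non-negative")
    p = np.zeros(nmax + 1)
    p[0] = math.exp(-m)
    if nmax == 0:
        return p
    # inv[j] = 1 / (j + 1); term for i is p[i] / (n - i + 1) = p[i] * inv[n-i]
    inv = 1.0 / (np.arange(nmax + 1) + 1.0)
    for n in range(1, nmax + 1):
        p[n] = (m / n) * float(np.dot(p[:n], inv[n:0:-1]))
    return p


def _thinning_matrix(eps: float, nmax: int, kmax: int) -> np.ndarray:
    """B[k, n] = P(Binomial(n, eps) = k) for observed counts after plating."""
    n = np.arange(nmax + 1)
    k = np.arange(kmax + 1)[:, None]
    return stats.binom.pmf(k, n[None, :], eps)


def thinned_pmf(m: float, eps: float, kmax: int, nmax: int | None = None) -> np.ndarray:
    """PMF of the plated (binomially thinned) mutant count up to kmax."""
    if eps >= 1.0:
        return luria_delbruck_pmf(m, kmax)
    if nmax is None:
        base = max(kmax, 10) / eps
        nmax = int(base * 1.5 + 8.0 * math.sqrt(base)) + 10
    p = luria_delbruck_pmf(m, nmax)
    return _thinning_matrix(eps, nmax, kmax) @ p


@dataclass(frozen=True)
class RateEstimate:
    """Mutation-rate estimate from one fluctuation assay.

    m_hat     expected mutation events per culture (whole-culture scale)
    rate      per cell per generation (m_hat / total culture cells)
    ci_low/high   95% profile-likelihood bounds on the rate
    boundary  True when every count is zero and only an upper bound is real
    """

    m_hat: float
    rate: float
    ci_low: float
    ci_high: float
    boundary: bool = False
    loglik: float = float("nan")

    def summary(self) -> str:
        flag = "  [boundary estimate: all counts zero]" if self.boundary else ""
        return (
            "Fluctuation-assay mutation rate (MSS maximum likelihood)\n"
            f"  m_hat (events/culture): {self.m_hat:.4g}\n"
            f"  rate (per cell per generation): {self.rate:.4g}\n"
            f"  95% CI: [{self.ci_low:.4g}, {self.ci_high:.4g}]{flag}\n"
        )


class FluctuationModel:
    """Luria-Delbruck model for one fluctuation assay; ``fit()`` -> RateEstimate.

    Parameters
    ----------
    assay : FluctuationAssay
    censor_at : counts at or above this value enter the likelihood as a
        censored tail P(count >= censor_at); bounds the O(n^2) MSS recursion
        while keeping jackpot cultures informative.
    """

    def __init__(self, assay: FluctuationAssay, censor_at: int = 1024):
        if len(assay.counts) < 2:
            raise ValueError("need at least 2 cultures to estimate a rate")
        if censor_at < 2:
            raise ValueError("censor_at must be >= 2")
        self.assay = assay
        self.censor_at = censor_at
        counts = np.asarray(assay.counts)
        self._censored = int((counts >= censor_at).sum())
        self._observed = counts[counts < censor_at]
        self._kmax = int(self._observed.max()) if self._observed.size else 0
        self._eps = assay.volume_fraction
        self._B = None
        if self._eps < 1.0:
            kk = max(self._kmax, self.censor_at - 1 if self._censored else 0, 10)
            base = kk / self._eps
            nmax = int(base * 1.5 + 8.0 * math.sqrt(base)) + 10
            self._B = _thinning_matrix(self._eps, nmax, kk)
            self._nmax = nmax

    def _pmf(self, m: float) -> np.ndarray:
        kmax = max(self._kmax, self.censor_at - 1 if self._censored else 0)
        if self._eps >= 1.0:
            return luria_delbruck_pmf(m, kmax)
        return self._B @ luria_delbruck_pmf(m, self._nmax)

    def loglik(self, m: float) -> float:
        if m < 0:
            return -np.inf
        q = self._pmf(m)
        ll = float(np.log(np.maximum(q[self._observed], 1e-300)).sum())
        if self._censored:
            tail = max(1.0 - float(q[: self.censor_at].sum()), 1e-300)
            ll += self._censored * math.log(tail)
        return ll

    def fit(self, ci: bool = True) -> RateEstimate:
        n_tot = self.assay.n_total_effective
        if self._censored == 0 and self._kmax == 0:
            # all-zero counts: likelihood maximized at m = 0; report the
            # profile upper bound only
            k = len(self.assay.counts)
            ll0 = self.loglik(0.0)
            m_hi = optimize.brentq(
                lambda m: self.loglik(m) - (ll0 - _PROFILE_DROP), 1e-12, 50.0
            )
            return RateEstimate(
                m_hat=0.0, rate=0.0, ci_low=0.0, ci_high=m_hi / n_tot,
                boundary=True, loglik=ll0,
            )
        res = optimize.minimize_scalar(
            lambda lm: -self.loglik(math.exp(lm)),
            bounds=(math.log(1e-4), math.log(500.0)),
            method="bounded",
            options={"xatol": 1e-6},
        )
        m_hat = math.exp(res.x)
        ll_max = -res.fun
        lo, hi = 0.0, float("inf")
        if ci:
            target = ll_max - _PROFILE_DROP

            def drop(m: float) -> float:
                return self.loglik(m) - target

            if drop(1e-6) < 0:
                lo = optimize.brentq(drop, 1e-6, m_hat)
            hi = optimize.brentq(drop, m_hat, max(10.0 * m_hat, m_hat + 5.0))
        return RateEstimate(
            m_hat=m_hat,
            rate=m_hat / n_tot,
            ci_low=lo / n_tot,
            ci_high=hi / n_tot,
            boundary=False,
            loglik=ll_max,
        )


def estimate_rate(
    assay: FluctuationAssay, ci: bool = True, censor_at: int = 1024
) -> RateEstimate:
    """MSS maximum-likelihood mutation rate for one assay (see FluctuationModel)."""
    return FluctuationModel(assay, censor_at=censor_at).fit(ci=ci)
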