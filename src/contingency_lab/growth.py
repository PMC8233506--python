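"""Baranyi-Roberts growth curves and two-strain virtual competitions.

The single-strain model is a Richards/logistic law modulated by a
physiological adjustment function that produces an explicit lag phase:

    dN/dt = r * alpha(t) * N * (1 - (N / k)^nu),
    alpha(t) = q0 / (q0 + exp(-v t)),

with initial density ``y0``, maximum specific growth rate ``r`` (per hour),
carrying capacity ``k``, deceleration exponent ``nu``, initial
physiological state ``q0`` and adjustment rate ``v``.  The lag time is
``lambda = ln(1 + 1/q0) / v`` (the time the adjustment integral loses to
full activation); a geometric tangent-construction lag is also provided.

Because alpha only rescales time, the single-strain trajectory has a closed
form: with adjusted time A(t) = t + ln((exp(-v t) + q0) / (1 + q0)) / v the
density follows the Richards solution

    N(t) = k * (1 + ((k/y0)^nu - 1) * exp(-r nu A(t)))^(-1/nu),

which this module evaluates directly (it satisfies the ODE to solver
precision and is far cheaper than numerical integration, which matters for
least-squares fitting).  The two-strain virtual competition couples both
strains through the summed density ("shared nutrient pool") and has no
closed form, so it is integrated numerically.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from scipy.stats import pearsonr

__all__ = [
    "GrowthParams",
    "GrowthFit",
    "VirtualCompetitionResult",
    "GrowthCurveModel",
    "br_trajectory",
    "fit_growth",
    "virtual_competition",
    "concordance",
]


@dataclass(frozen=True)
class GrowthParams:
    """Baranyi-Roberts parameter set for one strain (OD and hour units)."""

    y0: float   # initial density (OD)
    r: float    # max specific growth rate (/h)
    k: float    # carrying capacity (OD)
    nu: float   # deceleration (Richards) exponent
    q0: float   # initial physiological state (dimensionless)
    v: float    # adjustment rate (/h)

    def __post_init__(self) -> None:
        if not (self.y0 > 0 and self.r > 0 and self.nu > 0 and self.q0 > 0 and self.v > 0):
            raise ValueError(f"all parameters must be positive, got {self}")
        if self.k < self.y0:
            raise ValueError(f"carrying capacity k={self.k} below initial density y0={self.y0}")

    @property
    def lag(self) -> float:
        """Analytic lag time ln(1 + 1/q0) / v, in hours.

        Evaluated as softplus(-ln q0) / v, which stays finite for the
        extreme small-q0 / large-v parameter pairs the least-squares
        surface allows (they encode the same finite lag).
        """
        x = -math.log(self.q0)
        return (max(x, 0.0) + math.log1p(math.exp(-abs(x)))) / self.v

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "GrowthParams":
        return cls(**json.loads(text))


def _adjusted_time(t: np.ndarray, q0: float, v: float) -> np.ndarray:
    """A(t) = integral of alpha; time lost to physiological adjustment."""
    # log((e^{-vt} + q0)/(1 + q0)) computed stably for large v*t
    return t + (np.logaddexp(-v * t, math.log(q0)) - math.log1p(q0)) / v


def br_trajectory(params: GrowthParams, times) -> np.ndarray:
    """Noiseless Baranyi-Roberts density at each time point (hours)."""
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if np.any(t < 0) or np.any(np.diff(t) < 0):
        raise ValueError("times must be non-negative and sorted")
    a = _adjusted_time(t, params.q0, params.v)
    g = math.pow(params.k / params.y0, params.nu) - 1.0
    n = params.k * (1.0 + g * np.exp(-params.r * params.nu * a)) ** (-1.0 / params.nu)
    n[t == 0.0] = params.y0
    return n


@dataclass(frozen=True)
class GrowthFit:
    """Result of fitting one growth curve."""

    params: GrowthParams | None
    lag: float
    rss: float
    n_points: int
    success: bool = True
    message: str = ""
    geometric_lag: float = float("nan")

    def summary(self) -> str:
        if not self.success:
            return f"Growth fit FAILED: {self.message}\n"
        p = self.params
        return (
            "Baranyi-Roberts growth fit\n"
            f"  y0 = {p.y0:.4g} OD,  r = {p.r:.4g} /h,  k = {p.k:.4g} OD\n"
            f"  nu = {p.nu:.4g},  q0 = {p.q0:.4g},  v = {p.v:.4g} /h\n"
            f"  lag = {self.lag:.3f} h (geometric: {self.geometric_lag:.3f} h)\n"
            f"  rss = {self.rss:.4g} over {self.n_points} points\n"
        )


def _geometric_lag(params: GrowthParams) -> float:
    """Tangent-construction lag: intercept of the max-slope tangent to ln N."""
    t = np.linspace(0.0, 5.0 * (params.lag + math.log(params.k / params.y0) / params.r), 2001)
    ln_n = np.log(br_trajectory(params, t))
    slope = np.gradient(ln_n, t)
    i = int(np.argmax(slope))
    if slope[i] <= 0:
        return float("nan")
    return float(t[i] - (ln_n[i] - ln_n[0]) / slope[i])


# fixed multi-start grid over (q0, v) seeds; versioned so fits are reproducible
_START_GRID = [(1e-4, 1.0), (1e-3, 1.0), (1e-2, 1.0), (1e-1, 2.0), (1.0, 1.0), (1e-5, 2.0)]


class GrowthCurveModel:
    """Least-squares Baranyi-Roberts model for one (time, OD) curve.

    ``fit()`` minimizes squared OD residuals over all six parameters from a
    fixed multi-start grid (deterministic).  Parameters are optimized on a
    log scale, which enforces positivity without hard bounds.
    """

    def __init__(self, time_h, od):
        t = np.asarray(time_h, dtype=float)
        y = np.asarray(od, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("time and OD must be matching 1-D arrays")
        order = np.argsort(t)
        self.t, self.y = t[order], y[order]
        if self.t.size < 20:
            raise ValueError("need at least 20 points spanning lag through saturation")

    @classmethod
    def from_dataframe(cls, df, time_col: str = "time_h", od_col: str = "od"):
        return cls(df[time_col].to_numpy(), df[od_col].to_numpy())

    def _residuals(self, logx: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore"):
            y0, r, k, nu, q0, v = np.exp(logx)
        if not np.all(np.isfinite([y0, r, k, nu, q0, v])) or q0 == 0.0:
            return np.full_like(self.y, 1e3)
        try:
            p = GrowthParams(y0=y0, r=r, k=min(max(k, y0 * 1.0000001), 1e6), nu=nu, q0=q0, v=v)
        except ValueError:
            return np.full_like(self.y, 1e3)
        with np.errstate(over="ignore", invalid="ignore"):
            resid = br_trajectory(p, self.t) - self.y
        return np.where(np.isfinite(resid), resid, 1e3)

    def fit(self) -> GrowthFit:
        y = self.y
        span = float(y.max() - max(y.min(), 0.0))
        if y.max() <= 0 or span < 0.02 * max(y.max(), 1e-9) or span < 1e-4:
            return GrowthFit(None, float("nan"), float("nan"), y.size,
                             success=False, message="flat curve: no growth signal")
        # heuristic seeds from the data
        y0_init = max(float(np.median(y[: max(3, y.size // 20)])), 1e-6)
        k_init = float(y.max())
        # slope of log OD over the mid-growth window; readings near zero are
        # noise-dominated (and truncated at 0) so they are excluded
        window = (y > 0.1 * k_init) & (y < 0.6 * k_init)
        if window.sum() >= 3:
            coef = np.polyfit(self.t[window], np.log(y[window]), 1)
            r_init = float(coef[0])
        else:
            r_init = 0.5
        if not np.isfinite(r_init):
            r_init = 0.5
        r_init = float(np.clip(r_init, 0.05, 30.0))
        best = None
        for q0_init, v_scale in _START_GRID:
            x0 = np.log([y0_init, r_init, k_init, 1.0, q0_init, v_scale * r_init])
            try:
                sol = least_squares(self._residuals, x0, method="lm", max_nfev=4000)
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not np.all(np.isfinite(best.x)):
            return GrowthFit(None, float("nan"), float("nan"), y.size,
                             success=False, message="optimization failed from every start")
        y0, r, k, nu, q0, v = np.exp(best.x)
        try:
            params = GrowthParams(y0=y0, r=r, k=max(k, y0 * 1.0000001), nu=nu, q0=q0, v=v)
        except ValueError as err:
            return GrowthFit(None, float("nan"), float("nan"), y.size,
                             success=False, message=f"implausible parameters: {err}")
        rss = float(2.0 * best.cost)
        fitted = br_trajectory(params, self.t)
        if fitted[-1] < 2.0 * y0:
            return GrowthFit(params, params.lag, rss, y.size, success=False,
                             message="curve does not saturate above twice initial density")
        return GrowthFit(params, params.lag, rss, y.size,
                         geometric_lag=_geometric_lag(params))


def fit_growth(curve) -> GrowthFit:
    """Fit a Baranyi-Roberts model to a tidy (time_h, od) table or array pair."""
    if hasattr(curve, "columns"):
        return GrowthCurveModel.from_dataframe(curve).fit()
    t, y = curve
    return GrowthCurveModel(t, y).fit()


@dataclass(frozen=True)
class VirtualCompetitionResult:
    """Outcome of an in-silico two-strain competition over a shared pool."""

    w_virtual: float
    times: np.ndarray
    density_a: np.ndarray
    density_b: np.ndarray
    flagged: bool = False
    message: str = ""


def virtual_competition(
    params_a: GrowthParams,
    params_b: GrowthParams,
    horizon: float = 24.0,
    init_ratio: float = 0.5,
    y_total: float | None = None,
    n_points: int = 289,
) -> VirtualCompetitionResult:
    """Competition mediated only through growth parameters.

    Both strains draw down a common nutrient pool: each strain's growth
    decelerates with the *combined* density scaled by its own capacity,

        dN_i/dt = r_i alpha_i(t) N_i (1 - ((N_a + N_b) / k_i)^{nu_i}).

    The virtual relative fitness is the ratio of realized Malthusian
    parameters, w = ln(N_a(T)/N_a(0)) / ln(N_b(T)/N_b(0)), the same form
    used for plate-count competitions so the two are directly comparable.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if not 0 < init_ratio < 1:
        raise ValueError("init_ratio must lie strictly in (0, 1)")
    if y_total is None:
        y_total = params_a.y0 + params_b.y0
    na0, nb0 = init_ratio * y_total, (1.0 - init_ratio) * y_total

    pa, pb = params_a, params_b

    def rhs(t, y):
        na, nb = max(y[0], 0.0), max(y[1], 0.0)
        tot = na + nb
        aa = pa.q0 / (pa.q0 + math.exp(-pa.v * t))
        ab = pb.q0 / (pb.q0 + math.exp(-pb.v * t))
        dna = pa.r * aa * na * (1.0 - (tot / pa.k) ** pa.nu)
        dnb = pb.r * ab * nb * (1.0 - (tot / pb.k) ** pb.nu)
        # growth-only dynamics: once the pool is exhausted, densities hold
        return [max(dna, 0.0), max(dnb, 0.0)]

    t_eval = np.linspace(0.0, horizon, n_points)
    sol = solve_ivp(rhs, (0.0, horizon), [na0, nb0], t_eval=t_eval,
                    method="LSODA", rtol=1e-8, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"virtual competition integration failed: {sol.message}")
    na, nb = sol.y[0], sol.y[1]
    ga, gb = math.log(na[-1] / na0), math.log(nb[-1] / nb0)
    if abs(gb) < 1e-9 or abs(ga) < 1e-9:
        warnings.warn("a competitor shows zero net growth: virtual fitness undefined",
                      UserWarning, stacklevel=2)
        return VirtualCompetitionResult(float("nan"), sol.t, na, nb, flagged=True,
                                        message="zero net growth")
    return VirtualCompetitionResult(ga / gb, sol.t, na, nb)


def concordance(direct, virtual) -> tuple[float, float]:
    """Pearson correlation and mean |difference| between paired fitness lists.

    ``direct`` entries may be FitnessResult objects (their ``w_rel`` is used)
    or plain numbers; ``virtual`` entries VirtualCompetitionResult or numbers.
    """
    d = np.array([getattr(x, "w_rel", x) for x in direct], dtype=float)
    v = np.array([getattr(x, "w_virtual", x) for x in virtual], dtype=float)
    if d.shape != v.shape:
        raise ValueError(f"paired lists differ in length: {d.size} vs {v.size}")
    if d.size < 3:
        raise ValueError("need at least 3 pairs")
    mad = float(np.mean(np.abs(d - v)))
    if np.ptp(d) == 0 or np.ptp(v) == 0:
        warnings.warn("constant fitness values: correlation undefined",
                      UserWarning, stacklevel=2)
        return float("nan"), mad
    return float(pearsonr(d, v).statistic), mad
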