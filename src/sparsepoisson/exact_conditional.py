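"""Exact conditional Poisson inference for a single coefficient.

The distribution of the sufficient statistic ``T_j = sum_i x_ij y_i`` is
enumerated conditional on the sufficient statistics of all other
coefficients (intercept included, which fixes the total event count).  The
conditional pmf is ``P(T_j = t | beta_j) = c(t) e^{t beta_j} / sum_s c(s)
e^{s beta_j}`` with combinatorial weights ``c(t)``.  From it we compute the
maximum conditional likelihood estimate (MCLE), the median unbiased
estimate (MUE, the fallback when the observed statistic sits on the support
boundary), and exact / mid-p confidence intervals from the tail equations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .glm_core import Dataset

__all__ = [
    "CondDist",
    "ExactResult",
    "conditional_support",
    "mcle",
    "mue",
    "exact_ci",
    "fit_exact",
]

# feasibility envelope for the enumeration
MAX_TOTAL_EVENTS = 60
MAX_N = 250
MAX_K = 5

BETA_CAP = 40.0


@dataclass
class CondDist:
    """Exact conditional distribution of one sufficient statistic.

    ``support`` holds the attainable values of ``T_j`` (sorted) and
    ``logw`` the log combinatorial weights ``log c(t)``.
    """

    j: int
    t_obs: int
    support: np.ndarray
    logw: np.ndarray

    @property
    def degenerate(self) -> bool:
        return self.support.size == 1

    def logpmf(self, beta: float) -> np.ndarray:
        lw = self.logw + self.support * beta
        return lw - logsumexp(lw)

    def pmf(self, beta: float) -> np.ndarray:
        return np.exp(self.logpmf(beta))

    def mean(self, beta: float) -> float:
        return float(np.sum(self.pmf(beta) * self.support))

    def tail_ge(self, t: float, beta: float) -> float:
        """``P(T >= t | beta)``; increasing in ``beta``."""
        lp = self.logpmf(beta)
        mask = self.support >= t
        return float(np.exp(logsumexp(lp[mask]))) if mask.any() else 0.0

    def tail_le(self, t: float, beta: float) -> float:
        lp = self.logpmf(beta)
        mask = self.support <= t
        return float(np.exp(logsumexp(lp[mask]))) if mask.any() else 0.0

    def tail_ge_midp(self, t: float, beta: float) -> float:
        """``P(T > t) + 0.5 P(T = t)``."""
        p = self.pmf(beta)
        return float(p[self.support > t].sum() + 0.5 * p[self.support == t].sum())

    def tail_le_midp(self, t: float, beta: float) -> float:
        p = self.pmf(beta)
        return float(p[self.support < t].sum() + 0.5 * p[self.support == t].sum())


@dataclass
class ExactResult:
    """Point and interval estimates from the conditional distribution."""

    estimate: float | None
    estimate_type: str  # "MCLE" | "MUE" | "none"
    ci_exact: tuple[float, float] | None
    ci_midp: tuple[float, float] | None
    level: float
    dist: CondDist


def _as_int_matrix(X: np.ndarray, column_names) -> np.ndarray:
    Xi = np.round(X)
    bad = np.flatnonzero(np.abs(X - Xi).max(axis=0) > 1e-9)
    if bad.size:
        name = column_names[int(bad[0])]
        raise ValueError(
            f"exact conditional inference requires integer-valued covariates; "
            f"column {name!r} is not integer-valued"
        )
    return Xi.astype(int)


def conditional_support(data: Dataset, j: int) -> CondDist:
    """Enumerate the conditional distribution of ``T_j``.

    Rows sharing a covariate pattern are merged (their exposures add, by the
    multinomial theorem), then a depth-first recursion over patterns with
    memoization on the remaining nuisance-statistic budget accumulates the
    weights ``c(t) = sum_{y: constraints} prod_i E_i^{y_i} / y_i!`` with
    ``E_i = e^{z_i}``.
    """
    if j < 1 or j > data.k:
        raise ValueError("the conditioned-on set must include the intercept; "
                         "choose a non-intercept coefficient (1 <= j <= k)")
    if data.n > MAX_N or data.k > MAX_K:
        raise ValueError(
            f"enumeration guard exceeded (n <= {MAX_N}, k <= {MAX_K})")
    total = int(round(data.y.sum()))
    if total > MAX_TOTAL_EVENTS:
        raise ValueError(
            f"enumeration guard exceeded (sum(y) <= {MAX_TOTAL_EVENTS})")
    Xi = _as_int_matrix(data.X, data.column_names)
    y = data.y.astype(int)
    nuis_cols = [c for c in range(data.k + 1) if c != j]
    S = Xi[:, nuis_cols]  # nuisance stat contributions per row
    xj = Xi[:, j]
    t_nuis = tuple(int(v) for v in S.T @ y)
    t_obs = int(xj @ y)
    # exposures, normalized (uniform scaling only rescales every c(t) by the
    # same factor because the total count is fixed by the intercept stat)
    E = np.exp(data.z - data.z.max())
    E = E / E.sum()

    # merge identical covariate patterns: sum their exposures
    patterns: dict[tuple, float] = {}
    for i in range(data.n):
        key = tuple(Xi[i])
        patterns[key] = patterns.get(key, 0.0) + float(E[i])
    keys = list(patterns.keys())
    G = len(keys)
    g_s = [tuple(key[c] for c in nuis_cols) for key in keys]
    g_xj = [key[j] for key in keys]
    g_E = [patterns[key] for key in keys]
    nonneg = [bool(np.all(S[:, c] >= 0)) for c in range(len(nuis_cols))]
    ncols = len(nuis_cols)
    # position of the intercept among nuisance columns (j >= 1, so it is 0)
    icpt = nuis_cols.index(0)

    memo: dict[tuple, dict] = {}

    def rec(g: int, rem: tuple) -> dict:
        if g == G:
            return {0: 1.0} if all(r == 0 for r in rem) else {}
        key = (g, rem)
        hit = memo.get(key)
        if hit is not None:
            return hit
        s = g_s[g]
        Eg = g_E[g]
        cmax = rem[icpt]
        for c_idx in range(ncols):
            if nonneg[c_idx] and s[c_idx] > 0:
                cmax = min(cmax, rem[c_idx] // s[c_idx])
        out: dict[int, float] = {}
        w = 1.0
        for c in range(cmax + 1):
            if c > 0:
                w *= Eg / c
            new_rem = tuple(rem[i] - c * s[i] for i in range(ncols))
            if any(nonneg[i] and new_rem[i] < 0 for i in range(ncols)):
                continue
            sub = rec(g + 1, new_rem)
            if not sub:
                continue
            shift = c * g_xj[g]
            for t, sw in sub.items():
                out[t + shift] = out.get(t + shift, 0.0) + w * sw
        memo[key] = out
        return out

    weights = rec(0, t_nuis)
    if not weights:
        raise RuntimeError("enumeration produced no feasible outcome vectors")
    support = np.array(sorted(weights), dtype=float)
    w = np.array([weights[int(t)] for t in support])
    if np.any(w <= 0):
        raise RuntimeError("nonpositive conditional weight encountered")
    if t_obs not in weights:
        raise RuntimeError("observed statistic not in enumerated support")
    return CondDist(j=j, t_obs=t_obs, support=support, logw=np.log(w))


def _solve_monotone(fun, target: float, increasing: bool = True):
    """Root of ``fun(beta) = target`` for a monotone tail probability;
    returns ``+-inf`` when no root exists inside ``|beta| <= BETA_CAP``."""
    g = (lambda b: fun(b) - target) if increasing else (lambda b: target - fun(b))
    lo, hi = -BETA_CAP, BETA_CAP
    glo, ghi = g(lo), g(hi)
    if glo > 0:
        return -math.inf
    if ghi < 0:
        return math.inf
    return float(brentq(g, lo, hi, xtol=1e-8))


def mcle(dist: CondDist) -> float | None:
    """Maximum conditional likelihood estimate: the root of
    ``E[T | beta] = t_obs``.  ``None`` for degenerate distributions;
    ``+-inf`` when ``t_obs`` sits on the support boundary (no finite
    maximizer — callers fall back to the MUE)."""
    if dist.degenerate:
        return None
    if dist.t_obs <= dist.support.min():
        return -math.inf
    if dist.t_obs >= dist.support.max():
        return math.inf
    return _solve_monotone(dist.mean, float(dist.t_obs))


def mue(dist: CondDist) -> float | None:
    """Median unbiased estimate.

    At the support maximum it solves ``P(T >= t_obs | beta) = 1/2``; at the
    minimum, ``P(T <= t_obs | beta) = 1/2``; in the interior it is the
    midpoint of the two half-median solutions.
    """
    if dist.degenerate:
        return None
    t = dist.t_obs
    if t >= dist.support.max():
        return _solve_monotone(lambda b: dist.tail_ge(t, b), 0.5)
    if t <= dist.support.min():
        return _solve_monotone(lambda b: dist.tail_le(t, b), 0.5, increasing=False)
    b1 = _solve_monotone(lambda b: dist.tail_ge(t, b), 0.5)
    b2 = _solve_monotone(lambda b: dist.tail_le(t, b), 0.5, increasing=False)
    return 0.5 * (b1 + b2)


def exact_ci(dist: CondDist, level: float = 0.95, midp: bool = False):
    """Exact (or mid-p) confidence interval from the tail equations.

    Lower bound: ``P(T >= t_obs | beta) = alpha/2`` (mid-p counts half the
    observed point).  Upper bound: the mirrored lower-tail equation.  A
    bound is infinite when ``t_obs`` sits on the corresponding boundary.
    """
    if dist.degenerate:
        return None
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    t = dist.t_obs
    ge = dist.tail_ge_midp if midp else dist.tail_ge
    le = dist.tail_le_midp if midp else dist.tail_le
    if t <= dist.support.min() and not midp:
        lower = -math.inf  # P(T >= min) == 1 for every beta
    else:
        lower = _solve_monotone(lambda b: ge(t, b), alpha / 2.0)
    if t >= dist.support.max() and not midp:
        upper = math.inf
    else:
        upper = _solve_monotone(lambda b: le(t, b), alpha / 2.0, increasing=False)
    return (lower, upper)


def fit_exact(data: Dataset, j: int, level: float = 0.95) -> ExactResult:
    """Full exact-conditional analysis of coefficient ``j``."""
    dist = conditional_support(data, j)
    if dist.degenerate:
        return ExactResult(None, "none", None, None, level, dist)
    est = mcle(dist)
    if est is None or not math.isfinite(est):
        return ExactResult(
            mue(dist), "MUE",
            exact_ci(dist, level, midp=False),
            exact_ci(dist, level, midp=True),
            level, dist,
        )
    return ExactResult(
        est, "MCLE",
        exact_ci(dist, level, midp=False),
        exact_ci(dist, level, midp=True),
        level, dist,
    )
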