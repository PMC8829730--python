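"""Confidence intervals: Wald, profile likelihood on fixed-augmentation data,
and profile penalized likelihood (PPL).

Profile bounds are the roots of ``2 [l_max - l_profile(b)] = chi2_1(level)``
located by bracketed root-finding on each side of the point estimate.  A
profile that never crosses the cutoff before ``|b| = 40`` on the log scale is
reported as an infinite bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln
from scipy.stats import chi2, norm

from .glm_core import Dataset, FitResult, _ETA_CAP, hat_diagonals, fit_ml
from .firth import fit_fl, penalized_loglik

__all__ = ["IntervalEstimate", "wald_ci", "profile_ci"]

LOG_SCALE_CAP = 40.0


@dataclass
class IntervalEstimate:
    """Confidence bounds on the log-IRR scale.

    ``lower``/``upper`` are arrays (Wald, all coefficients) or floats
    (profile methods, a single coefficient ``j``).  ``+-inf`` entries are
    mirrored by the ``*_infinite`` flags.  ``reliable`` is set to False for
    Wald intervals computed from a separated fit.
    """

    lower: np.ndarray | float
    upper: np.ndarray | float
    level: float
    method: str
    j: int | None = None
    lower_infinite: np.ndarray | bool = False
    upper_infinite: np.ndarray | bool = False
    reliable: bool = True


def wald_ci(fit: FitResult, level: float = 0.95) -> IntervalEstimate:
    """``beta_j +- z_{1-alpha/2} SE_j`` for every coefficient."""
    if fit.cov is None or not np.all(np.isfinite(fit.cov)):
        raise ValueError("fit has no usable covariance matrix")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    zq = norm.ppf(0.5 + level / 2.0)
    se = fit.se
    return IntervalEstimate(
        lower=fit.beta - zq * se,
        upper=fit.beta + zq * se,
        level=level,
        method="wald",
        reliable=not fit.separated,
    )


def _plain_loglik(y_work, X, z, beta):
    eta = np.minimum(X @ beta + z, _ETA_CAP)
    return float(np.sum(-np.exp(eta) + eta * y_work) - np.sum(gammaln(y_work + 1.0)))


class _ProfileEvaluator:
    """Maximize the (penalized) likelihood over the remaining coefficients
    with coefficient ``j`` held fixed, warm-starting from the previous call.
    """

    def __init__(self, data: Dataset, j: int, kind: str, y_work=None,
                 tol: float = 1e-8, max_iter: int = 200):
        self.data = data
        self.j = j
        self.kind = kind  # "ppl" or "plain"
        self.y_work = data.y if y_work is None else np.asarray(y_work, float)
        self.tol = tol
        self.max_iter = max_iter
        self.others = np.array([c for c in range(data.k + 1) if c != j])
        self.warm = None

    def _objective(self, beta):
        if self.kind == "ppl":
            return penalized_loglik(self.data, beta)
        return _plain_loglik(self.y_work, self.data.X, self.data.z, beta)

    def __call__(self, bj: float, warm=None) -> float:
        data, j = self.data, self.j
        X, z = data.X, data.z
        beta = np.array(
            warm if warm is not None
            else self.warm if self.warm is not None
            else np.zeros(data.k + 1),
            dtype=float,
        )
        beta[j] = bj
        if self.others.size == 0:
            self.warm = beta
            return self._objective(beta)
        obj = self._objective(beta)
        for _ in range(self.max_iter):
            eta = np.minimum(X @ beta + z, _ETA_CAP)
            mu = np.exp(eta)
            if self.kind == "ppl":
                h = hat_diagonals(data, beta)
                resid = data.y + h / 2.0 - mu
            else:
                resid = self.y_work - mu
            grad = (X.T @ resid)[self.others]
            if np.max(np.abs(grad)) < self.tol:
                break
            info = X.T @ (X * mu[:, None])
            sub = info[np.ix_(self.others, self.others)]
            try:
                step = np.linalg.solve(sub, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(sub, grad, rcond=None)[0]
            factor = 1.0
            cand = beta.copy()
            cand[self.others] += step
            new_obj = self._objective(cand)
            halvings = 0
            while new_obj < obj - 1e-12 and halvings < 40:
                factor *= 0.5
                halvings += 1
                cand = beta.copy()
                cand[self.others] += factor * step
                new_obj = self._objective(cand)
            beta = cand
            if np.linalg.norm(factor * step) < 1e-12:
                obj = new_obj
                break
            obj = new_obj
        self.warm = beta.copy()
        return self._objective(beta)


def _find_bound(devfun, bhat_j, side, cut, first_step=0.5, cap=LOG_SCALE_CAP):
    """Walk outward with doubling steps until the profile deviance crosses
    the cutoff, then polish by Brent root-finding."""
    inner = bhat_j
    step = first_step
    while True:
        outer = bhat_j + side * step
        if abs(outer) > cap:
            return side * np.inf
        if devfun(outer) - cut > 0.0:
            break
        inner = outer
        step *= 2.0
    root = brentq(lambda b: devfun(b) - cut, min(inner, outer), max(inner, outer),
                  xtol=1e-10, rtol=8.9e-16)
    return float(root)


def profile_ci(
    data: Dataset,
    fit: FitResult,
    j: int,
    mode: str = "ppl",
    level: float = 0.95,
) -> IntervalEstimate:
    """Profile confidence interval for coefficient ``j``.

    Modes
    -----
    ``ppl``
        Profile of the Firth-penalized likelihood; the leverages are
        recomputed at every fixed value of ``beta_j``.
    ``pl_fixed``
        Profile of the ordinary likelihood of the h/2-augmented data with
        the pseudo counts frozen at the FL solution (the fast approximation
        used in practice; slightly narrower than ``ppl``).
    ``ml_pl``
        Ordinary profile likelihood around an ML fit (used for ML and, on
        augmented data, for the data-augmentation Bayesian fit).
    """
    if not 0 <= j <= data.k:
        raise ValueError(f"coefficient index {j} out of range")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    cut = float(chi2.ppf(level, 1))  # computed, not hard-coded

    if mode in ("ppl", "pl_fixed"):
        if fit.method == "fl":
            fl = fit
        else:
            fl = fit_fl(data)
        bhat = fl.beta
        if mode == "ppl":
            lmax = fl.penloglik
            evaluator = _ProfileEvaluator(data, j, "ppl")
        else:
            y_aug = data.y + fl.hat / 2.0
            lmax = _plain_loglik(y_aug, data.X, data.z, fl.beta)
            evaluator = _ProfileEvaluator(data, j, "plain", y_work=y_aug)
    elif mode == "ml_pl":
        if fit.method not in ("ml", "bda"):
            fit = fit_ml(data)
        bhat = fit.beta
        lmax = fit.loglik
        evaluator = _ProfileEvaluator(data, j, "plain")
    else:
        raise ValueError(f"unknown profile mode {mode!r}")

    warm0 = bhat.copy()

    def devfun(bj):
        val = evaluator(bj, warm=warm0.copy())
        return 2.0 * (lmax - val)

    se = fit.se[j] if np.all(np.isfinite(fit.cov)) else 1.0
    first_step = max(min(se, 5.0), 0.25)
    lower = _find_bound(devfun, bhat[j], -1, cut, first_step)
    upper = _find_bound(devfun, bhat[j], +1, cut, first_step)
    return IntervalEstimate(
        lower=lower,
        upper=upper,
        level=level,
        method=mode,
        j=j,
        lower_infinite=bool(np.isinf(lower)),
        upper_infinite=bool(np.isinf(upper)),
    )
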