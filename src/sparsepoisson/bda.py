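"""Bayesian data augmentation (BDA): mean-zero normal priors on the
log-IRRs encoded as pseudo-observations, with maximum-posterior estimation
by ordinary ML on the augmented data.

A symmetric 95% prior interval ``(1/U, U)`` for the IRR implies prior
standard deviation ``log(U)/1.96`` and variance ``v``.  One pseudo-row per
covariate carries value ``1/S`` for that covariate (0 elsewhere, including
the intercept), event count ``S^2/v`` and offset ``log(S^2/v)``; to order
``1/S`` its likelihood contribution is the quadratic ``-beta_j^2 / (2v)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm_core import Dataset, FitResult, hat_diagonals, loglik, _safe_inverse
from .intervals import IntervalEstimate, profile_ci

__all__ = ["PriorSpec", "prior_to_pseudo", "build_bda_augmentation", "fit_bda",
           "bda_profile_ci", "default_prior_upper"]

_Z95 = 1.96  # conventional rounded quantile used in the prior construction


@dataclass
class PriorSpec:
    """Normal prior for one log-IRR, given by a symmetric 95% IRR interval.

    Either ``upper`` (the upper IRR limit; the lower limit is ``1/upper``)
    or ``sd`` (the prior standard deviation on the log scale) must be set.
    """

    upper: float | None = None
    sd: float | None = None
    S: float = 10_000.0

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError("approximation constant S must be >= 1")
        if self.sd is None:
            if self.upper is None or self.upper <= 1.0:
                raise ValueError("prior upper IRR limit must exceed 1")
            self.sd = float(np.log(self.upper) / _Z95)
        elif self.sd <= 0:
            raise ValueError("prior standard deviation must be positive")

    @property
    def lower(self) -> float | None:
        return None if self.upper is None else 1.0 / self.upper

    @property
    def v(self) -> float:
        return self.sd**2

    @property
    def pseudo_count(self) -> float:
        return self.S**2 / self.v


def default_prior_upper(covariate_kind: str) -> float:
    """Default prior interval widths: (1/1000, 1000) for binary/ordinal
    covariates, (1/100, 100) for continuous ones."""
    if covariate_kind in ("binary", "ordinal"):
        return 1000.0
    if covariate_kind == "continuous":
        return 100.0
    raise ValueError(f"unknown covariate kind {covariate_kind!r}")


def prior_to_pseudo(prior: PriorSpec, j: int, k: int):
    """Pseudo-observation encoding the prior on coefficient ``j``.

    Returns ``(x_row, y, z)``: covariate ``j`` takes value ``1/S``, every
    other column (intercept included) is 0, the count is ``S^2/v`` and the
    offset ``log(S^2/v)``.  The intercept never receives a prior (``j >= 1``).
    """
    if j < 1 or j > k:
        raise ValueError("priors apply to non-intercept covariates only (1 <= j <= k)")
    x_row = np.zeros(k + 1)
    x_row[j] = 1.0 / prior.S
    y = prior.pseudo_count
    return x_row, y, float(np.log(y))


def _normalize_priors(priors, k: int) -> list[PriorSpec]:
    if isinstance(priors, PriorSpec):
        return [priors] * k
    priors = list(priors)
    if len(priors) != k:
        raise ValueError(f"need one prior per covariate: expected {k}, got {len(priors)}")
    return priors


def build_bda_augmentation(data: Dataset, priors) -> Dataset:
    """Original rows plus one prior pseudo-row per covariate."""
    k = data.k
    priors = _normalize_priors(priors, k)
    rows, counts, offs = [], [], []
    for j, prior in enumerate(priors, start=1):
        x_row, y, z = prior_to_pseudo(prior, j, k)
        rows.append(x_row)
        counts.append(y)
        offs.append(z)
    X_aug = np.vstack([data.X, np.array(rows)])
    y_aug = np.concatenate([data.y, np.array(counts)])
    z_aug = np.concatenate([data.z, np.array(offs)])
    return Dataset(
        y=y_aug,
        X=X_aug,
        z=z_aug,
        column_names=list(data.column_names),
        require_intercept=False,
        require_integer=False,
    )


def _bda_newton(data: Dataset, priors: list[PriorSpec], start,
                max_iter: int = 100, score_tol: float = 1e-9):
    """Newton for the prior-augmented likelihood with the pseudo-row terms
    evaluated via ``expm1`` (the naive ``y - mu`` difference of two ~S^2/v
    counts loses ~6 digits to cancellation).

    The pseudo-row of covariate ``j`` contributes, up to a constant,
    ``-(S^2/v) [expm1(b/S) - b/S]`` to the log-likelihood,
    ``-(S/v) expm1(b/S)`` to the score and ``(1/v) exp(b/S)`` to the
    information diagonal — exactly the augmented-data ML equations.
    """
    X, y, z = data.X, data.y, data.z
    S = np.array([p.S for p in priors])
    v = np.array([p.v for p in priors])

    def obj(b):
        eta = X @ b + z
        with np.errstate(over="ignore"):
            ll = float(np.sum(-np.exp(eta) + eta * y))
        pen = -np.sum((S**2 / v) * (np.expm1(b[1:] / S) - b[1:] / S))
        val = ll + float(pen)
        return -np.inf if np.isnan(val) else val

    beta = np.array(start, dtype=float)
    ll = obj(beta)
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.minimum(X @ beta + z, 500.0)
        mu = np.exp(eta)
        grad = X.T @ (y - mu)
        grad[1:] += -(S / v) * np.expm1(beta[1:] / S)
        if np.max(np.abs(grad)) < score_tol:
            break
        info = X.T @ (X * mu[:, None])
        info[np.arange(1, len(beta)), np.arange(1, len(beta))] += (
            np.exp(beta[1:] / S) / v
        )
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        factor = 1.0
        new_ll = obj(beta + step)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 40:
            factor *= 0.5
            halvings += 1
            new_ll = obj(beta + factor * step)
        beta = beta + factor * step
        ll = new_ll
        if np.linalg.norm(factor * step) < 1e-12:
            break
    eta = np.minimum(X @ beta + z, 500.0)
    mu = np.exp(eta)
    grad = X.T @ (y - mu)
    grad[1:] += -(S / v) * np.expm1(beta[1:] / S)
    info = X.T @ (X * mu[:, None])
    info[np.arange(1, len(beta)), np.arange(1, len(beta))] += (
        np.exp(beta[1:] / S) / v
    )
    converged = bool(np.max(np.abs(grad)) < score_tol)
    return beta, info, converged, it


def fit_bda(data: Dataset, priors, start=None) -> FitResult:
    """Maximum-posterior fit: ML on the prior-augmented data.

    The pseudo-rows have intercept column 0, so they contribute nothing to
    the intercept score and the fitted total over the original rows equals
    ``sum(y)`` exactly.  The estimate is finite under separation whenever
    every covariate carries a prior.
    """
    data.check_full_rank()
    from .separation import detect_separation

    prior_list = _normalize_priors(priors, data.k)
    aug = build_bda_augmentation(data, prior_list)
    if start is None:
        start = np.zeros(data.k + 1)
        denom = np.exp(data.z).sum()
        start[0] = np.log(max(data.y.sum(), 0.5) / denom)
    beta, info, converged, iterations = _bda_newton(data, prior_list, start)
    res = FitResult(
        beta=beta,
        mu_hat=np.exp(aug.X @ beta + aug.z),
        cov=_safe_inverse(info),
        hat=np.full(aug.n, np.nan),
        loglik=loglik(aug, beta),
        penloglik=None,
        method="bda",
        converged=converged,
        separated=False,
        iterations=iterations,
        column_names=list(aug.column_names),
    )
    mu_hat = np.exp(data.X @ beta + data.z)
    return FitResult(
        beta=beta,
        mu_hat=mu_hat,
        cov=res.cov,
        hat=hat_diagonals(data, beta),
        loglik=loglik(data, beta),
        penloglik=None,
        method="bda",
        converged=res.converged,
        separated=detect_separation(data).separated,
        iterations=res.iterations,
        column_names=list(data.column_names),
        extras={"augmented_data": aug, "augmented_fit": res,
                "priors": prior_list},
    )


def bda_profile_ci(
    data: Dataset,
    priors,
    j: int,
    level: float = 0.95,
    fit: FitResult | None = None,
) -> IntervalEstimate:
    """Profile-likelihood CI on the augmented (posterior) likelihood."""
    if fit is None or "augmented_fit" not in fit.extras:
        fit = fit_bda(data, priors)
    aug = fit.extras["augmented_data"]
    aug_fit = fit.extras["augmented_fit"]
    ci = profile_ci(aug, aug_fit, j, mode="ml_pl", level=level)
    ci.method = "bda_pl"
    return ci
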