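"""Firth-penalized Poisson regression (FL) and its prediction-debiased
variants FLAC (added covariate) and FLIC (intercept correction).

FL maximizes the Jeffreys-penalized log-likelihood
``l*(beta) = l(beta) + 0.5 log|X'WX|``; equivalently it is ML on counts
augmented by half the leverages, ``y_i + h_i/2``.  The intercept equation of
the modified score forces ``sum(mu_hat) = sum(y) + (k+1)/2``, i.e. FL
overpredicts the total count by ``(k+1)/2``.  FLAC and FLIC recalibrate the
fitted totals back to ``sum(y)`` without touching the non-intercept
coefficients; for Poisson regression the two constructions coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm_core import (
    MAX_ITER,
    SCORE_TOL,
    STEP_TOL,
    Dataset,
    FitResult,
    _default_start,
    _eta,
    _safe_inverse,
    _ETA_CAP,
    hat_diagonals,
    information,
    loglik,
    newton_poisson,
)

__all__ = [
    "AugmentedDataset",
    "penalized_loglik",
    "fit_fl",
    "fit_flac",
    "fit_flic",
]


@dataclass
class AugmentedDataset:
    """Original data stacked with one pseudo-row per observation.

    Pseudo-rows replicate the covariates and offset of their source row but
    carry event count ``h_i/2`` (leverages from the FL solution) and are
    marked by the added covariate ``G`` (0 original / 1 pseudo).
    """

    data: Dataset
    pseudo_counts: np.ndarray
    G: np.ndarray
    source: np.ndarray


def penalized_loglik(data: Dataset, beta) -> float:
    """``l(beta) + 0.5 log|X'WX|``; ``-inf`` if the information is singular."""
    ll = loglik(data, beta)
    info = information(data, beta)
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0 or not np.isfinite(logdet):
        return -np.inf
    return ll + 0.5 * logdet


def _fl_newton(data, start, max_iter, score_tol, step_tol):
    """Newton on the penalized likelihood: gradient ``X'(y + h/2 - mu)``,
    Hessian approximated by ``-X'WX``, with step-halving on ``l*``."""
    X, y, z = data.X, data.y, data.z
    beta = np.array(start, dtype=float)
    pll = penalized_loglik(data, beta)
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.minimum(X @ beta + z, _ETA_CAP)
        mu = np.exp(eta)
        h = hat_diagonals(data, beta)
        grad = X.T @ (y + h / 2.0 - mu)
        if np.max(np.abs(grad)) < score_tol:
            # one polish step for quadratic-accuracy roots
            info = X.T @ (X * mu[:, None])
            try:
                polish = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                polish = np.linalg.lstsq(info, grad, rcond=None)[0]
            if penalized_loglik(data, beta + polish) >= pll - 1e-12:
                beta = beta + polish
            break
        info = X.T @ (X * mu[:, None])
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        factor = 1.0
        new_pll = penalized_loglik(data, beta + step)
        halvings = 0
        while new_pll < pll - 1e-12 and halvings < 40:
            factor *= 0.5
            halvings += 1
            new_pll = penalized_loglik(data, beta + factor * step)
        beta = beta + factor * step
        if np.linalg.norm(factor * step) < step_tol:
            pll = new_pll
            break
        pll = new_pll
    h = hat_diagonals(data, beta)
    mu = np.exp(np.minimum(X @ beta + z, _ETA_CAP))
    grad = X.T @ (y + h / 2.0 - mu)
    converged = bool(np.max(np.abs(grad)) < score_tol)
    return beta, converged, it


def fit_fl(
    data: Dataset,
    start=None,
    method: str = "newton",
    max_iter: int = MAX_ITER,
    score_tol: float = 1e-8,
    step_tol: float = STEP_TOL,
) -> FitResult:
    """Firth-penalized fit.

    ``method='newton'`` solves the modified score equations directly,
    recomputing the leverages at every iterate.  ``method='augmentation'``
    alternates full ML fits on counts ``y + h/2`` with leverage updates; the
    two routes converge to the same root.
    """
    data.check_full_rank()
    from .separation import detect_separation

    separated = detect_separation(data).separated
    if start is None:
        start = _default_start(data)
    if method == "newton":
        beta, converged, iterations = _fl_newton(
            data, start, max_iter, score_tol, step_tol
        )
    elif method == "augmentation":
        beta = np.array(start, dtype=float)
        converged = False
        iterations = 0
        for outer in range(1, max_iter + 1):
            h = hat_diagonals(data, beta)
            new_beta, inner_conv, inner_it = newton_poisson(
                data.y + h / 2.0, data, beta, max_iter=max_iter,
                score_tol=min(score_tol, 1e-9), step_tol=step_tol,
            )
            iterations += inner_it
            delta = np.max(np.abs(new_beta - beta))
            beta = new_beta
            if delta < 1e-10 and inner_conv:
                converged = True
                break
    else:
        raise ValueError(f"unknown FL method {method!r}")
    mu_hat = np.exp(_eta(data, beta))
    info = information(data, beta)
    return FitResult(
        beta=beta,
        mu_hat=mu_hat,
        cov=_safe_inverse(info),
        hat=hat_diagonals(data, beta),
        loglik=loglik(data, beta),
        penloglik=penalized_loglik(data, beta),
        method="fl",
        converged=converged,
        separated=separated,
        iterations=iterations,
        column_names=list(data.column_names),
    )


def build_flac_augmentation(data: Dataset, fl: FitResult) -> AugmentedDataset:
    """Stack pseudo-rows with counts ``h_i/2`` and the added covariate G."""
    n, p = data.n, data.k + 1
    h = fl.hat
    X_aug = np.zeros((2 * n, p + 1))
    X_aug[:n, :p] = data.X
    X_aug[n:, :p] = data.X
    X_aug[n:, p] = 1.0  # G column
    y_aug = np.concatenate([data.y, h / 2.0])
    z_aug = np.concatenate([data.z, data.z])
    aug = Dataset(
        y=y_aug,
        X=X_aug,
        z=z_aug,
        column_names=list(data.column_names) + ["G"],
        require_integer=False,
    )
    return AugmentedDataset(
        data=aug, pseudo_counts=h / 2.0, G=X_aug[:, p], source=np.arange(n)
    )


def fit_flac(data: Dataset, fl: FitResult | None = None, **kwargs) -> FitResult:
    """FL with added covariate: ML on the h/2-augmented data with an extra
    coefficient for G; predictions set G=0, so the fitted total over the
    original rows equals ``sum(y)`` while the non-intercept coefficients
    stay at their FL values."""
    if fl is None:
        fl = fit_fl(data, **kwargs)
    augmentation = build_flac_augmentation(data, fl)
    n, p = data.n, data.k + 1
    total = data.y.sum()
    s = (data.k + 1) / 2.0
    # closed-form warm start: shift the FL intercept, gamma from the G score.
    # With no observed events the augmented ML has no finite intercept; the
    # fit below then returns its (flagged) last iterate, slopes still finite.
    start = np.zeros(p + 1)
    start[:p] = fl.beta
    if total > 0:
        start[0] += np.log(total / (total + s))
        start[p] = np.log(s / (total + s)) - np.log(total / (total + s))
    from .glm_core import fit_ml

    res = fit_ml(augmentation.data, start=start, check_separation=False,
                 score_tol=1e-10)
    beta = res.beta[:p]
    gamma = float(res.beta[p])
    mu_hat = np.exp(data.X @ beta + data.z)
    return FitResult(
        beta=beta,
        mu_hat=mu_hat,
        cov=res.cov[:p, :p],
        hat=hat_diagonals(data, beta),
        loglik=loglik(data, beta),
        penloglik=None,
        method="flac",
        converged=res.converged,
        separated=fl.separated,
        iterations=res.iterations,
        column_names=list(data.column_names),
        extras={
            "gamma_flac": gamma,
            "fl_beta": fl.beta,
            "augmentation": augmentation,
        },
    )


def fit_flic(data: Dataset, fl: FitResult | None = None, **kwargs) -> FitResult:
    """FL with intercept correction: keep the FL slopes and shift the
    intercept by ``delta = log(sum(y) / sum(mu_FL))`` (the closed-form ML
    solution of the one-parameter offset model)."""
    if fl is None:
        fl = fit_fl(data, **kwargs)
    total = data.y.sum()
    if total <= 0:
        raise ValueError("FLIC intercept correction is undefined when sum(y) == 0")
    delta = float(np.log(total / fl.mu_hat.sum()))
    beta = fl.beta.copy()
    beta[0] += delta
    mu_hat = fl.mu_hat * (total / fl.mu_hat.sum())
    return FitResult(
        beta=beta,
        mu_hat=mu_hat,
        cov=fl.cov,  # FL covariance carried over; see intervals for PPL CIs
        hat=fl.hat,  # leverages are invariant to an intercept shift
        loglik=loglik(data, beta),
        penloglik=None,
        method="flic",
        converged=fl.converged,
        separated=fl.separated,
        iterations=fl.iterations,
        column_names=list(data.column_names),
        extras={"delta_flic": delta, "fl_beta": fl.beta},
    )
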