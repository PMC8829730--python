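"""Core Poisson GLM machinery: likelihood, score, information, leverages, ML fit.

The :class:`Dataset` container is what every fitter in this package consumes:
integer event counts ``y``, a design matrix ``X`` whose first column is the
intercept, and a per-observation log-offset ``z`` (e.g. log exposure or the
log of a rate multiplier).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln

__all__ = [
    "Dataset",
    "FitResult",
    "RankDeficientError",
    "loglik",
    "score",
    "information",
    "hat_diagonals",
    "fit_ml",
]

MAX_ITER = 100
SCORE_TOL = 1e-6
STEP_TOL = 1e-8

# linear predictors above this are clipped inside the optimizer only, to keep
# intermediate iterates finite; reported quantities are never clipped
_ETA_CAP = 500.0


class RankDeficientError(ValueError):
    """Design matrix does not have full column rank."""


@dataclass
class Dataset:
    """Count data for a Poisson regression with offset.

    Parameters
    ----------
    y : array_like
        Nonnegative event counts, one per observation.  Must be integers
        unless ``require_integer`` is ``False`` (used internally for
        augmented pseudo-data).
    X : array_like
        ``n x (k+1)`` design matrix; the first column must be all ones
        unless ``require_intercept`` is ``False``.
    z : array_like, optional
        Log-offset per observation (defaults to zeros).  The coefficient of
        the offset is fixed at one.
    column_names : list of str, optional
        Labels for the columns of ``X``.
    """

    y: np.ndarray
    X: np.ndarray
    z: np.ndarray | None = None
    column_names: list[str] | None = None
    require_intercept: bool = True
    require_integer: bool = True

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.y.ndim != 1:
            raise ValueError("y must be one-dimensional")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]} entries"
            )
        if self.z is None:
            self.z = np.zeros_like(self.y)
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != self.y.shape:
            raise ValueError("offset z must have one entry per observation")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y contains non-finite values")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("offset contains non-finite values")
        if np.any(self.y < 0):
            bad = int(np.flatnonzero(self.y < 0)[0])
            raise ValueError(f"negative count in row {bad}")
        if self.require_integer and np.any(self.y != np.round(self.y)):
            bad = int(np.flatnonzero(self.y != np.round(self.y))[0])
            raise ValueError(f"non-integer count in row {bad}")
        if self.require_intercept and not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first column of X must be the intercept (all ones)")
        if self.column_names is None:
            self.column_names = ["(Intercept)"] + [
                f"x{j}" for j in range(1, self.X.shape[1])
            ]
        if len(self.column_names) != self.X.shape[1]:
            raise ValueError("column_names length must match number of columns of X")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1] - 1

    @classmethod
    def from_multiplier(
        cls,
        y,
        X,
        multiplier,
        column_names=None,
        **kwargs,
    ) -> "Dataset":
        """Build a dataset from a positive rate multiplier (exposure) column.

        The multiplier enters the model as a log-offset.
        """
        multiplier = np.asarray(multiplier, dtype=float)
        if np.any(multiplier <= 0):
            bad = int(np.flatnonzero(multiplier <= 0)[0])
            raise ValueError(f"nonpositive multiplier in row {bad}")
        return cls(y=y, X=X, z=np.log(multiplier), column_names=column_names, **kwargs)

    def check_full_rank(self) -> None:
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise RankDeficientError("design matrix X is rank deficient")


@dataclass
class FitResult:
    """Fitted Poisson regression.

    ``beta`` has length ``k+1``; ``mu_hat`` are the fitted means
    ``exp(X beta + z)``; ``cov`` is the inverse Fisher information at the
    estimate; ``hat`` are the leverages (hat-matrix diagonals).
    """

    beta: np.ndarray
    mu_hat: np.ndarray
    cov: np.ndarray
    hat: np.ndarray
    loglik: float
    penloglik: float | None
    method: str
    converged: bool
    separated: bool
    iterations: int
    column_names: list[str] | None = None
    extras: dict = field(default_factory=dict)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, np.inf))

    @property
    def irr(self) -> np.ndarray:
        return np.exp(self.beta)


def _check_beta(data: Dataset, beta) -> np.ndarray:
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.shape[0] != data.k + 1:
        raise ValueError(f"beta must have length {data.k + 1}, got {beta.shape[0]}")
    if not np.all(np.isfinite(beta)):
        raise ValueError("beta contains non-finite values")
    return beta


def _eta(data: Dataset, beta: np.ndarray) -> np.ndarray:
    return data.X @ beta + data.z


def loglik(data: Dataset, beta) -> float:
    """Poisson log-likelihood, including the ``-log(y_i!)`` constants."""
    beta = _check_beta(data, beta)
    eta = _eta(data, beta)
    with np.errstate(over="ignore"):
        mu = np.exp(eta)
    ll = float(np.sum(-mu + eta * data.y) - np.sum(gammaln(data.y + 1.0)))
    if np.isnan(ll):  # only reachable via overflow; report as -inf, never NaN
        return -np.inf
    return ll


def score(data: Dataset, beta) -> np.ndarray:
    """Score vector ``X'(y - mu)``."""
    beta = _check_beta(data, beta)
    mu = np.exp(np.minimum(_eta(data, beta), _ETA_CAP))
    return data.X.T @ (data.y - mu)


def information(data: Dataset, beta) -> np.ndarray:
    """Fisher information ``X' W X`` with ``W = diag(mu)``."""
    beta = _check_beta(data, beta)
    mu = np.exp(np.minimum(_eta(data, beta), _ETA_CAP))
    return data.X.T @ (data.X * mu[:, None])


def hat_diagonals(data: Dataset, beta) -> np.ndarray:
    """Diagonals of ``W^{1/2} X (X'WX)^{-1} X' W^{1/2}``.

    They lie in ``(0, 1]`` and sum to ``k+1`` at every ``beta``.
    """
    beta = _check_beta(data, beta)
    mu = np.exp(np.minimum(_eta(data, beta), _ETA_CAP))
    A = data.X * np.sqrt(mu)[:, None]
    info = A.T @ A
    try:
        c = cho_factor(info)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises ValueError
        raise RankDeficientError("X'WX is singular") from exc
    except ValueError as exc:
        raise RankDeficientError("X'WX is singular") from exc
    B = cho_solve(c, A.T)
    return np.einsum("ij,ji->i", A, B)


def _solve_step(info: np.ndarray, grad: np.ndarray) -> np.ndarray:
    try:
        return cho_solve(cho_factor(info), grad)
    except (np.linalg.LinAlgError, ValueError):
        return np.linalg.lstsq(info, grad, rcond=None)[0]


def _default_start(data: Dataset) -> np.ndarray:
    total = data.y.sum()
    denom = np.exp(data.z).sum()
    beta = np.zeros(data.k + 1)
    beta[0] = np.log(max(total, 0.5) / denom)
    return beta


def newton_poisson(
    y_work: np.ndarray,
    data: Dataset,
    start: np.ndarray,
    max_iter: int = MAX_ITER,
    score_tol: float = SCORE_TOL,
    step_tol: float = STEP_TOL,
):
    """Newton-Raphson with step-halving for a Poisson likelihood on counts
    ``y_work`` (possibly non-integer) over the design of ``data``.

    Returns ``(beta, converged, iterations)``.  Under separation the
    log-likelihood has no maximizer; iterates then drift and the routine
    returns the last iterate after ``max_iter`` steps.
    """

    X, z = data.X, data.z
    beta = np.array(start, dtype=float)
    lgam = np.sum(gammaln(y_work + 1.0))

    def obj(b):
        eta = np.minimum(X @ b + z, _ETA_CAP)
        return float(np.sum(-np.exp(eta) + eta * y_work) - lgam)

    ll = obj(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.minimum(X @ beta + z, _ETA_CAP)
        mu = np.exp(eta)
        grad = X.T @ (y_work - mu)
        if np.max(np.abs(grad)) < score_tol:
            # one full polish step (quadratic convergence) before declaring
            info = X.T @ (X * mu[:, None])
            polish = _solve_step(info, grad)
            if obj(beta + polish) >= ll - 1e-12:
                beta = beta + polish
            converged = True
            break
        info = X.T @ (X * mu[:, None])
        step = _solve_step(info, grad)
        # step-halving: insist on not decreasing the objective
        factor = 1.0
        new_ll = obj(beta + step)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 40:
            factor *= 0.5
            halvings += 1
            new_ll = obj(beta + factor * step)
        beta = beta + factor * step
        if np.linalg.norm(factor * step) < step_tol and new_ll <= ll + 1e-13:
            ll = new_ll
            break
        ll = new_ll
    else:
        it = max_iter
    # final score check
    eta = np.minimum(X @ beta + z, _ETA_CAP)
    mu = np.exp(eta)
    grad = X.T @ (y_work - mu)
    converged = bool(np.max(np.abs(grad)) < score_tol)
    return beta, converged, it


def _safe_inverse(info: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(info)


def fit_ml(
    data: Dataset,
    start=None,
    max_iter: int = MAX_ITER,
    score_tol: float = SCORE_TOL,
    step_tol: float = STEP_TOL,
    check_separation: bool = True,
) -> FitResult:
    """Maximum likelihood Poisson fit.

    If the data are separated the ML estimate does not exist; the last
    Newton iterate is returned with ``separated=True`` (no exception),
    mirroring what standard GLM software reports at its final iteration.
    """
    data.check_full_rank()
    separated = False
    if check_separation:
        from .separation import detect_separation

        separated = detect_separation(data).separated
    if start is None:
        start = _default_start(data)
    beta, converged, iterations = newton_poisson(
        data.y, data, start, max_iter=max_iter, score_tol=score_tol, step_tol=step_tol
    )
    mu_hat = np.exp(_eta(data, beta))
    info = information(data, beta)
    cov = _safe_inverse(info)
    try:
        hat = hat_diagonals(data, beta)
    except RankDeficientError:
        hat = np.full(data.n, np.nan)
    return FitResult(
        beta=beta,
        mu_hat=mu_hat,
        cov=cov,
        hat=hat,
        loglik=loglik(data, beta),
        penloglik=None,
        method="ml",
        converged=converged,
        separated=separated,
        iterations=iterations,
        column_names=list(data.column_names),
    )
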