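"""Sparse-event simulation engine: factorial covariate generator, intercept
calibration to a target marginal incidence, dataset sampling with a
zero-truncated Poisson rate multiplier, and scenario-level performance
metrics (bias, scaled RMSE/RMSPE, one-sided coverage, power).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from .glm_core import Dataset, fit_ml
from .firth import fit_fl, fit_flac
from .bda import PriorSpec, bda_profile_ci, fit_bda
from .intervals import profile_ci, wald_ci
from .separation import detect_separation

__all__ = [
    "ScenarioConfig",
    "correlation_matrix",
    "generate_covariates",
    "compute_isr",
    "calibrate_intercept",
    "sample_multiplier",
    "generate_dataset",
    "run_scenario",
    "summarize",
    "NUISANCE_BASE",
    "COVARIATE_KINDS",
]

# pairwise correlations of the latent normals (symmetric closure applied)
_CORR_PAIRS = {
    (1, 2): 0.5, (1, 7): 0.5,
    (3, 4): -0.5, (3, 5): -0.3,
    (4, 5): 0.5, (4, 7): 0.3, (4, 8): 0.5, (4, 9): 0.3,
    (5, 8): 0.3, (5, 9): 0.3,
    (6, 7): -0.3, (6, 8): 0.3,
    (8, 9): 0.5,
}

COVARIATE_KINDS = ["binary"] * 4 + ["ordinal"] * 2 + ["continuous"] * 4

# latent columns resampled below their marginal 99th percentile
_TRUNCATED_COLS = (7, 8)  # z8, z9 (0-based)


def correlation_matrix() -> np.ndarray:
    """10x10 latent correlation matrix; checked positive definite."""
    sigma = np.eye(10)
    for (a, b), r in _CORR_PAIRS.items():
        sigma[a - 1, b - 1] = r
        sigma[b - 1, a - 1] = r
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("latent correlation matrix is not positive definite") from exc
    return sigma


def _trunc(x: np.ndarray) -> np.ndarray:
    """Drop the non-integer part (truncation toward zero)."""
    return np.trunc(x)


def generate_covariates(
    n: int,
    k: int = 10,
    rng: np.random.Generator | int | None = None,
    corr: np.ndarray | None = None,
) -> np.ndarray:
    """Draw the first ``k`` covariates of the factorial design.

    Latent ``Z`` is multivariate normal with the design's correlation
    matrix; two log-normal sources are truncated at their 99th percentile by
    inverse-CDF resampling (conditional distribution, not clamping) before
    the threshold/truncation transforms are applied.
    """
    if k not in (2, 5, 10) and not 1 <= k <= 10:
        raise ValueError("k must be between 1 and 10")
    rng = np.random.default_rng(rng)
    sigma = correlation_matrix() if corr is None else np.asarray(corr, float)
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not positive definite") from exc
    Z = rng.standard_normal((n, 10)) @ L.T
    for c in _TRUNCATED_COLS:
        u = ndtr(Z[:, c])
        Z[:, c] = ndtri(0.99 * u)
    X = np.empty((n, 10))
    X[:, 0] = Z[:, 0] > 1.28
    X[:, 1] = Z[:, 1] > 0.35
    X[:, 2] = Z[:, 2] > 0
    X[:, 3] = Z[:, 3] > 0
    X[:, 4] = (Z[:, 4] >= -1.2).astype(float) + (Z[:, 4] >= 0.75)
    X[:, 5] = (Z[:, 5] >= 0.5).astype(float) + (Z[:, 5] >= 1.5)
    X[:, 6] = _trunc(10.0 * Z[:, 6] + 55.0)
    X[:, 7] = _trunc(np.maximum(0.0, 100.0 * np.exp(Z[:, 7]) - 20.0))
    X[:, 8] = _trunc(np.maximum(0.0, 80.0 * np.exp(Z[:, 8]) - 20.0))
    X[:, 9] = _trunc(10.0 * Z[:, 9] + 120.0)
    return X[:, :k]


def compute_isr(column: np.ndarray) -> float:
    """Intersextile range: the 5/6 quantile minus the 1/6 quantile."""
    column = np.asarray(column, float)
    isr = float(np.quantile(column, 5.0 / 6.0) - np.quantile(column, 1.0 / 6.0))
    if isr <= 0:
        raise ValueError("intersextile range is zero (constant column)")
    return isr


# effect sizes for the nuisance covariates; continuous entries are divided
# by the covariate's intersextile range
NUISANCE_BASE = [0.69, -0.69, 0.69, 0.35, -0.35, 0.69, -0.69, 0.69, -0.69]


def coefficient_vector(k: int, beta1: float, isr: dict[int, float] | None = None) -> np.ndarray:
    """Full coefficient vector (without intercept) for the first k covariates."""
    beta = [beta1] + list(NUISANCE_BASE[: k - 1])
    for idx in range(6, k):  # 0-based continuous covariates x7..x10
        if isr is None or (idx + 1) not in isr:
            raise ValueError(f"ISR required for continuous covariate x{idx + 1}")
        beta[idx] = beta[idx] / isr[idx + 1]
    return np.array(beta, dtype=float)


@dataclass
class ScenarioConfig:
    """One simulation cell of the factorial design."""

    k: int
    epv: float
    beta1: float
    reps: int = 500
    seed: int = 1
    incidence: float = 0.1
    psi_mean: float = 1.6
    # "underlying": psi ~ Poisson(psi_mean) conditioned on psi >= 1
    # "truncated": the zero-truncated mean itself equals psi_mean
    psi_convention: str = "underlying"
    calibration_n: int = 200_000

    def __post_init__(self) -> None:
        if self.psi_convention not in ("underlying", "truncated"):
            raise ValueError("psi_convention must be 'underlying' or 'truncated'")

    @property
    def n(self) -> int:
        return int(round(self.epv * self.k / self.incidence))


def _psi_lambda(config: ScenarioConfig) -> float:
    if config.psi_convention == "underlying":
        return config.psi_mean
    m = config.psi_mean
    if m <= 1.0:
        raise ValueError("zero-truncated mean must exceed 1")
    return float(brentq(lambda lam: lam / (1 - np.exp(-lam)) - m, 1e-8, 50.0))


def sample_multiplier(n: int, config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Zero-truncated Poisson rate multiplier (>= 1 always)."""
    lam = _psi_lambda(config)
    psi = rng.poisson(lam, size=n).astype(float)
    zero = psi == 0
    while np.any(zero):
        psi[zero] = rng.poisson(lam, size=int(zero.sum()))
        zero = psi == 0
    return psi


def _calibration_rng(config: ScenarioConfig) -> np.random.Generator:
    # dedicated stream so coefficients are identical across reps
    return np.random.default_rng([config.seed, 0])


def calibrate_intercept(config: ScenarioConfig, calibration_n: int | None = None,
                        seed=None):
    """Choose the intercept so the Monte-Carlo mean of
    ``exp(beta0 + x beta) * psi`` equals the target incidence.

    Returns ``(beta0, beta, isr)`` where ``beta`` is the non-intercept
    coefficient vector and ``isr`` maps continuous covariate numbers to
    their intersextile ranges (empty when ``k <= 6``).
    """
    m = calibration_n or config.calibration_n
    rng = np.random.default_rng(seed) if seed is not None else _calibration_rng(config)
    X = generate_covariates(m, k=config.k, rng=rng)
    isr = {jj: compute_isr(X[:, jj - 1]) for jj in range(7, config.k + 1)}
    beta = coefficient_vector(config.k, config.beta1, isr)
    psi = sample_multiplier(m, config, rng)
    mean_rate = float(np.mean(np.exp(X @ beta) * psi))
    if not np.isfinite(mean_rate) or mean_rate <= 0:
        raise RuntimeError("intercept calibration failed: degenerate mean rate")
    beta0 = float(np.log(config.incidence) - np.log(mean_rate))
    return beta0, beta, isr


def generate_dataset(config: ScenarioConfig, beta0: float, beta: np.ndarray,
                     rng: np.random.Generator):
    """One simulated dataset plus its vector of true means."""
    n = config.n
    X = generate_covariates(n, k=config.k, rng=rng)
    psi = sample_multiplier(n, config, rng)
    mu = np.exp(beta0 + X @ beta) * psi
    y = rng.poisson(mu)
    design = np.column_stack([np.ones(n), X])
    names = ["(Intercept)"] + [f"x{j}" for j in range(1, config.k + 1)]
    data = Dataset(y=y, X=design, z=np.log(psi), column_names=names)
    return data, mu


def _bda_priors(k: int) -> list[PriorSpec]:
    return [PriorSpec(upper=default_upper(j)) for j in range(1, k + 1)]


def default_upper(j: int) -> float:
    return 1000.0 if j <= 6 else 100.0


def _exact_feasible(data: Dataset) -> bool:
    from . import exact_conditional as ec

    return (
        data.n <= min(ec.MAX_N, 250)
        and data.k <= min(ec.MAX_K, 5)
        and data.y.sum() <= ec.MAX_TOTAL_EVENTS
        and np.allclose(data.X, np.round(data.X))
    )


def run_scenario(
    config: ScenarioConfig,
    methods=("ml", "fl", "flac", "bda"),
    compute_ci: bool = False,
    level: float = 0.95,
):
    """Run every replication of a scenario and aggregate the metrics.

    Returns ``(summary, per_rep)`` data frames.  Randomness is fully
    reproducible from ``(config.seed, rep)``; the calibration sample uses a
    dedicated child stream.
    """
    beta0, beta, _isr = calibrate_intercept(config)
    beta1_true = float(beta[0])
    priors = _bda_priors(config.k)
    records = []
    for rep in range(config.reps):
        rng = np.random.default_rng([config.seed, 1 + rep])
        data, mu_true = generate_dataset(config, beta0, beta, rng)
        separated = detect_separation(data).separated
        fl_fit = None
        for m in methods:
            rec = {
                "rep": rep, "method": m, "separated": separated,
                "n": config.n, "beta1_true": beta1_true,
                "mue_fallback": False,
            }
            try:
                if m == "ml":
                    fit = fit_ml(data, check_separation=False)
                    fit.separated = separated
                elif m == "fl":
                    fl_fit = fit = fit_fl(data)
                elif m == "flac":
                    if fl_fit is None:
                        fl_fit = fit_fl(data)
                    fit = fit_flac(data, fl=fl_fit)
                elif m == "bda":
                    fit = fit_bda(data, priors)
                elif m == "exact":
                    if not _exact_feasible(data):
                        rec["skipped"] = "enumeration infeasible"
                        records.append(rec)
                        continue
                    from .exact_conditional import fit_exact

                    er = fit_exact(data, 1, level=level)
                    rec["beta1_hat"] = (
                        np.nan if er.estimate is None else float(er.estimate)
                    )
                    rec["mue_fallback"] = er.estimate_type == "MUE"
                    rec["degenerate"] = er.estimate_type == "none"
                    if compute_ci and er.ci_midp is not None:
                        rec["lower"], rec["upper"] = er.ci_midp
                        rec["lower_exact"], rec["upper_exact"] = er.ci_exact
                    records.append(rec)
                    continue
                else:
                    raise ValueError(f"unknown method {m!r}")
            except Exception as exc:  # per-rep skip, mirrored in the summary
                rec["skipped"] = repr(exc)
                records.append(rec)
                continue
            rec["beta1_hat"] = float(fit.beta[1])
            rec["converged"] = fit.converged
            rec["sum_mu"] = float(fit.mu_hat.sum())
            rec["mspe"] = float(np.mean((fit.mu_hat - mu_true) ** 2))
            if compute_ci:
                try:
                    if m == "ml":
                        ci = wald_ci(fit, level=level)
                        rec["lower"] = float(ci.lower[1])
                        rec["upper"] = float(ci.upper[1])
                    elif m in ("fl", "flac"):
                        ci = profile_ci(data, fl_fit, 1, mode="pl_fixed", level=level)
                        rec["lower"], rec["upper"] = ci.lower, ci.upper
                    elif m == "bda":
                        ci = bda_profile_ci(data, priors, 1, level=level, fit=fit)
                        rec["lower"], rec["upper"] = ci.lower, ci.upper
                except Exception as exc:
                    rec["ci_failed"] = repr(exc)
            records.append(rec)
    per_rep = pd.DataFrame(records)
    return summarize(per_rep, beta1_true, config.n), per_rep


def summarize(per_rep: pd.DataFrame, beta1_true: float, n: int) -> pd.DataFrame:
    """Aggregate per-replication records into the scenario metrics table."""
    rows = []
    for method, g in per_rep.groupby("method", sort=False):
        b = g.get("beta1_hat")
        b = pd.Series(dtype=float) if b is None else b.dropna()
        row = {
            "method": method,
            "reps_used": int(len(b)),
            "bias_beta1": float(b.mean() - beta1_true) if len(b) else np.nan,
            "rmse_beta1_sqrt_n": (
                float(np.sqrt(np.mean((b - beta1_true) ** 2)) * np.sqrt(n))
                if len(b) else np.nan
            ),
            "finite_rate": float(np.isfinite(b).mean()) if len(b) else np.nan,
            "separation_rate": float(g["separated"].mean()),
        }
        if "mspe" in g and g["mspe"].notna().any():
            row["rmspe_sqrt_n"] = float(
                np.sqrt(g["mspe"].dropna().mean()) * np.sqrt(n)
            )
        if "mue_fallback" in g:
            row["mue_fallback_rate"] = float(g["mue_fallback"].fillna(False).mean())
        if "lower" in g and g["lower"].notna().any():
            gl = g.dropna(subset=["lower", "upper"])
            row["coverage_left"] = float((gl["lower"] <= beta1_true).mean())
            row["coverage_right"] = float((gl["upper"] >= beta1_true).mean())
            row["power"] = float(((gl["lower"] > 0) | (gl["upper"] < 0)).mean())
            widths = (gl["upper"] - gl["lower"]).replace([np.inf, -np.inf], np.nan)
            row["median_ci_width"] = float(widths.median())
        rows.append(row)
    return pd.DataFrame(rows)
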