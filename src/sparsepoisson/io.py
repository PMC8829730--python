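"""CSV readers/writers, result serialization and bundled example fixtures."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .glm_core import Dataset, FitResult

__all__ = ["read_dataset", "write_results", "make_fixtures"]


def read_dataset(
    path,
    outcome: str,
    covariates: list[str] | None = None,
    multiplier: str | None = None,
    offset: str | None = None,
) -> Dataset:
    """Read a CSV file into a :class:`Dataset`.

    ``outcome`` names the count column.  ``multiplier`` names a positive
    exposure column (entered as a log-offset); ``offset`` names a column
    already on the log scale; at most one of the two may be given.  Columns
    not listed in ``covariates`` (default: every remaining column) become
    regressors; non-numeric columns are expanded to dummies with the first
    level in alphabetical order as the reference.
    """
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    if multiplier is not None and offset is not None:
        raise ValueError("give either a multiplier or a log-offset column, not both")
    for col in filter(None, [outcome, multiplier, offset]):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    if covariates is None:
        covariates = [c for c in df.columns if c not in (outcome, multiplier, offset)]
    for col in covariates:
        if col not in df.columns:
            raise ValueError(f"covariate column {col!r} not found in {path}")

    y = df[outcome].to_numpy()
    if not np.issubdtype(np.asarray(y).dtype, np.number):
        raise ValueError(f"outcome column {outcome!r} is not numeric")
    frac = np.asarray(y, dtype=float) % 1 != 0
    if frac.any():
        raise ValueError(f"non-integer count in row {int(np.flatnonzero(frac)[0])}")

    blocks, names = [], []
    for col in covariates:
        s = df[col]
        if np.issubdtype(s.dtype, np.number):
            blocks.append(s.to_numpy(dtype=float)[:, None])
            names.append(col)
        else:
            levels = sorted(s.astype(str).unique())
            for lev in levels[1:]:  # first level alphabetically is the reference
                blocks.append((s.astype(str) == lev).to_numpy(dtype=float)[:, None])
                names.append(f"{col}[{lev}]")
    X = np.hstack([np.ones((len(df), 1))] + blocks) if blocks else np.ones((len(df), 1))
    column_names = ["(Intercept)"] + names

    z = None
    if multiplier is not None:
        mult = df[multiplier].to_numpy(dtype=float)
        if np.any(mult <= 0):
            raise ValueError(
                f"nonpositive multiplier in row {int(np.flatnonzero(mult <= 0)[0])}"
            )
        z = np.log(mult)
    elif offset is not None:
        z = df[offset].to_numpy(dtype=float)
    return Dataset(y=y, X=X, z=z, column_names=column_names)


def _config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_results(
    fit: FitResult,
    path,
    intervals=None,
    config: dict | None = None,
    seed: int | None = None,
):
    """Write a coefficient table CSV plus a JSON run manifest.

    Returns ``(csv_path, manifest_path)``.
    """
    path = Path(path)
    names = fit.column_names or [f"b{j}" for j in range(len(fit.beta))]
    table = pd.DataFrame(
        {
            "term": names,
            "estimate": fit.beta,
            "irr": np.exp(fit.beta),
            "method": fit.method,
        }
    )
    if intervals is not None:
        if np.ndim(intervals.lower) == 0:
            lo = np.full(len(fit.beta), np.nan)
            hi = np.full(len(fit.beta), np.nan)
            lo[intervals.j] = intervals.lower
            hi[intervals.j] = intervals.upper
        else:
            lo, hi = np.asarray(intervals.lower), np.asarray(intervals.upper)
        table["ci_lower"] = lo
        table["ci_upper"] = hi
        table["irr_ci_lower"] = np.exp(lo)
        table["irr_ci_upper"] = np.exp(hi)
        table["ci_method"] = intervals.method
        table["ci_level"] = intervals.level
    table.to_csv(path, index=False, float_format="%.10g")
    manifest = {
        "seed": seed,
        "version": __version__,
        "method": fit.method,
        "converged": bool(fit.converged),
        "separated": bool(fit.separated),
        "config_hash": _config_hash(config or {}),
        "config": config or {},
    }
    manifest_path = path.with_suffix(path.suffix + ".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path, manifest_path


def make_fixtures(outdir, seed: int = 0) -> dict[str, Path]:
    """Write the bundled example CSVs and return their paths.

    Includes the Austrian COVID-19 testing table, a symmetric two-group toy,
    and random datasets that are verified to be separated / non-separated.
    """
    from .examples import covid_table
    from .glm_core import fit_ml
    from .separation import detect_separation

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths: dict[str, Path] = {}

    covid = covid_table()
    paths["covid"] = outdir / "covid_testing.csv"
    covid.to_csv(paths["covid"], index=False)

    twogroup = pd.DataFrame(
        {"group": [0, 1], "events": [1, 1], "exposure": [1.0, 1.0]}
    )
    paths["twogroup"] = outdir / "twogroup.csv"
    twogroup.to_csv(paths["twogroup"], index=False)

    # separated by construction: no events whenever x1 == 1
    while True:
        n = 30
        x1 = rng.integers(0, 2, n)
        x2 = rng.integers(0, 2, n)
        y = rng.poisson(0.8, n)
        y[x1 == 1] = 0
        if y.sum() >= 3 and x1.sum() >= 2:
            X = np.column_stack([np.ones(n), x1, x2])
            ds = Dataset(y=y, X=X, column_names=["(Intercept)", "x1", "x2"])
            if detect_separation(ds).separated:
                break
    sep = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
    paths["separated"] = outdir / "separated.csv"
    sep.to_csv(paths["separated"], index=False)

    # non-separated: events forced into every covariate pattern
    while True:
        n = 40
        x1 = rng.integers(0, 2, n)
        x2 = rng.integers(0, 2, n)
        y = rng.poisson(1.0, n)
        X = np.column_stack([np.ones(n), x1, x2])
        ds = Dataset(y=y, X=X, column_names=["(Intercept)", "x1", "x2"])
        if not detect_separation(ds).separated:
            fit = fit_ml(ds, check_separation=False)
            if fit.converged:
                break
    nonsep = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
    paths["nonseparated"] = outdir / "nonseparated.csv"
    nonsep.to_csv(paths["nonseparated"], index=False)
    return paths
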