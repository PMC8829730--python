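"""Detection of separation (nonexistence of the Poisson ML estimate).

The ML estimate fails to exist if and only if there is a nonzero direction
``gamma`` with ``x_i . gamma == 0`` on every row with events and
``x_i . gamma <= 0`` on every row without events, strictly negative
somewhere.  That condition is decided here by a bounded linear program and,
when separation is present, the optimizing direction is returned as a
certificate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .glm_core import Dataset

__all__ = ["SeparationReport", "detect_separation"]


@dataclass
class SeparationReport:
    """Outcome of the separation check.

    ``gamma`` is a certificate direction when ``separated`` is true (the
    condition is scale-invariant, so it is only defined up to a positive
    multiple).  ``strict_rows`` lists the zero-count rows where
    ``x_i . gamma`` is strictly negative — those are the observations whose
    fitted means are driven to zero by a diverging ML path.
    """

    separated: bool
    gamma: np.ndarray | None
    strict_rows: np.ndarray

    def to_dict(self) -> dict:
        return {
            "separated": bool(self.separated),
            "gamma": None if self.gamma is None else [float(g) for g in self.gamma],
            "strict_rows": [int(i) for i in self.strict_rows],
        }


def detect_separation(data: Dataset, tol: float = 1e-7) -> SeparationReport:
    """Decide separation via a linear-program feasibility search.

    Maximizes ``sum_{y_i=0} -x_i . gamma`` subject to ``x_i . gamma == 0``
    on event rows, ``x_i . gamma <= 0`` on zero rows and box bounds
    ``|gamma_j| <= 1`` (harmless by scale invariance).  The data are
    separated iff the optimum exceeds ``tol``.

    The verdict depends only on the design and on which rows have events —
    not on the offsets or on the magnitudes of the positive counts.
    """
    if data.n == 0:
        raise ValueError("cannot assess separation of an empty dataset")
    X = data.X
    pos = data.y > 0
    zero = ~pos
    p = X.shape[1]
    if not np.any(zero):
        # every equality row pins gamma to the null space of X; with full
        # rank that is {0}, and without zero rows there is no strict row.
        return SeparationReport(False, None, np.array([], dtype=int))
    c = X[zero].sum(axis=0)  # minimize sum over zero rows of x . gamma
    A_ub = X[zero]
    b_ub = np.zeros(A_ub.shape[0])
    A_eq = X[pos] if np.any(pos) else None
    b_eq = np.zeros(int(pos.sum())) if np.any(pos) else None
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=[(-1.0, 1.0)] * p,
        method="highs",
    )
    if res.status != 0:
        raise RuntimeError(f"separation LP failed: {res.message}")
    if res.fun >= -tol:
        return SeparationReport(False, None, np.array([], dtype=int))
    gamma = np.asarray(res.x, dtype=float)
    vals = X @ gamma
    strict = np.flatnonzero(zero & (vals < -tol))
    return SeparationReport(True, gamma, strict)
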