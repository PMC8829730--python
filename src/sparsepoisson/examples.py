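"""Small worked-example datasets used in the documentation and tests."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .glm_core import Dataset

__all__ = ["covid_table", "covid_dataset", "two_group_dataset"]


def covid_table() -> pd.DataFrame:
    """Austrian COVID-19 testing series (spring 2020): positives and number
    tested among employees of supermarkets, nursing homes and hospitals."""
    return pd.DataFrame(
        {
            "employment": ["Supermarket", "Nursing home", "Hospital"],
            "positive": [0, 3, 3],
            "tested": [352, 444, 365],
        }
    )


def covid_dataset() -> Dataset:
    """The testing table as a 3-row dataset: intercept, nursing-home and
    hospital dummies (supermarket is the reference), offset log(tested)."""
    t = covid_table()
    X = np.array([[1.0, 0.0, 0.0], [1.0, 1.0, 0.0], [1.0, 0.0, 1.0]])
    return Dataset(
        y=t["positive"].to_numpy(),
        X=X,
        z=np.log(t["tested"].to_numpy(dtype=float)),
        column_names=["(Intercept)", "nursing", "hospital"],
    )


def two_group_dataset(y=(1, 1), exposure=(1.0, 1.0)) -> Dataset:
    """Two observations, one binary covariate."""
    X = np.array([[1.0, 0.0], [1.0, 1.0]])
    return Dataset(
        y=np.asarray(y),
        X=X,
        z=np.log(np.asarray(exposure, dtype=float)),
        column_names=["(Intercept)", "group"],
    )
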