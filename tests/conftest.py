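import numpy as np
import pytest

from sparsepoisson import Dataset, covid_dataset, detect_separation


def random_dataset(rng, n=30, k=2, rate=1.0, with_offset=True, ensure=None,
                   max_tries=200):
    """Random small dataset with binary covariates.

    ensure: None | "separated" | "nonseparated"
    """
    for _ in range(max_tries):
        X = np.column_stack([np.ones(n)] + [rng.integers(0, 2, n) for _ in range(k)])
        if np.linalg.matrix_rank(X) < k + 1:
            continue
        z = np.log(rng.uniform(0.5, 2.0, n)) if with_offset else np.zeros(n)
        beta = rng.normal(0, 0.5, k + 1)
        mu = np.exp(X @ beta + z) * rate
        y = rng.poisson(mu)
        ds = Dataset(y=y, X=X, z=z)
        if ensure is None:
            return ds
        sep = detect_separation(ds).separated
        if ensure == "separated" and sep:
            return ds
        if ensure == "nonseparated" and not sep and y.sum() > 0:
            return ds
    raise RuntimeError(f"could not build a {ensure} dataset in {max_tries} tries")


@pytest.fixture
def covid():
    return covid_dataset()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
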