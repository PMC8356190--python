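import numpy as np
import pandas as pd
import pytest

import tmescore as tm


@pytest.fixture()
def rng():
    return np.random.default_rng(20210810)


@pytest.fixture(scope="session")
def fixture_panel():
    """Deterministic NanoString-style cohort on the packaged synthetic panel."""
    return tm.make_fixture_panel()


@pytest.fixture()
def small_matrix(rng):
    """10 genes x 8 samples log2-scale matrix."""
    genes = [f"G{i}" for i in range(10)]
    samples = [f"S{i}" for i in range(8)]
    return tm.ExpressionMatrix(genes, samples, rng.normal(7, 1, size=(10, 8)), "log2")


@pytest.fixture(scope="session")
def default_cohort():
    return tm.simulate_cohort(tm.SyntheticCohortSpec(seed=3))


def pc1_oracle(values: np.ndarray, genes: list[str]) -> np.ndarray:
    """Independent PC1 score: full eigendecomposition of the gene-gene
    covariance of the z-scored rows, same orientation rule as the package."""
    sd = values.std(axis=1, ddof=1)
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    x = z.T  # samples x genes
    cov = np.cov(x, rowvar=False, ddof=1)
    w, v = np.linalg.eigh(np.atleast_2d(cov))
    lead = v[:, np.argmax(w)]
    s = lead.sum()
    if s < 0:
        lead = -lead
    elif s == 0:
        first = int(np.argsort(np.asarray(genes, dtype=object))[0])
        if lead[first] < 0:
            lead = -lead
    return x @ lead
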