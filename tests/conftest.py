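import warnings

import numpy as np
import pandas as pd
import pytest

from propp.case import generate_case_fixture, run_case_analysis
from propp.data import SubjectTable
from propp.power_prior import WeightedCounts


@pytest.fixture
def vemurafenib_counts() -> SubjectTable:
    """Covariate-free table with the published response counts: trial 75/132
    responders, external 129/241."""
    df = pd.DataFrame(
        {"z": [1] * 132 + [0] * 241, "y": [1] * 75 + [0] * 57 + [1] * 129 + [0] * 112}
    )
    return SubjectTable(df)


@pytest.fixture
def toy_counts() -> WeightedCounts:
    return WeightedCounts(a_e=0.5, b_e=0.0, a_0=2.0, b_0=1.0)


@pytest.fixture
def no_signal_table() -> SubjectTable:
    """Covariates independent of membership, equal arms."""
    rng = np.random.default_rng(11)
    n = 400
    z = np.r_[np.ones(n, dtype=int), np.zeros(n, dtype=int)]
    x = rng.normal(size=(2 * n, 3))
    y = rng.binomial(1, 0.5, size=2 * n)
    return SubjectTable.from_arrays(z, y, x)


@pytest.fixture(scope="session")
def case_fixture() -> SubjectTable:
    return generate_case_fixture(seed=2024)


@pytest.fixture(scope="session")
def case_report(case_fixture):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return run_case_analysis(case_fixture, seed=2024)
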