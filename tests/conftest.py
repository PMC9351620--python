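import numpy as np
import pandas as pd
import pytest

from ckdbioage import build_builtin_indices, generate, load_fixture


@pytest.fixture(scope="session")
def builtin_indices():
    return build_builtin_indices()


@pytest.fixture(scope="session")
def table4():
    return load_fixture("table4_correlations")


@pytest.fixture(scope="session")
def table6():
    return load_fixture("table6_training")


@pytest.fixture(scope="session")
def age_corrs(table4):
    """Age row of the published correlation matrix, age itself dropped."""
    return table4.loc["age"].drop("age")


@pytest.fixture(scope="session")
def synthetic_cohort():
    """A 2000-patient synthetic cohort for recovery checks."""
    return generate(n=2000, seed=20260923)


@pytest.fixture(scope="session")
def small_cohort():
    return generate(n=190, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(4221)


@pytest.fixture()
def normal_cohort_row():
    """A patient whose every biomarker sits at its normal reference."""
    return {
        "age": 60.0, "bmi": 21.75, "sbp": 125.0, "dbp": 82.0,
        "egfr": 95.0, "ctca": 0.0,
    }
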