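import numpy as np
import pandas as pd
import pytest

from vocclass import FeatureTable, SyntheticConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def tiny_table():
    """6 samples x 3 abundance features, one PSA covariate, labels 3/3."""
    idx = [f"S{i}" for i in range(6)]
    values = pd.DataFrame(
        {
            "voc_a": [0.0, 3.2, 0.0001, 5.0, 0.0, 1.0],
            "voc_b": [1.0, 0.0, 2.0, 0.0, 4.0, 0.0],
            "voc_c": [5.0, 10.0, 7.0, 9.0, 6.0, 8.0],
        },
        index=idx,
    )
    labels = pd.Series(["cancer"] * 3 + ["control"] * 3, index=idx, name="class")
    covs = pd.DataFrame({"psa": [6.0, 10.0, 4.0, 12.0, 3.0, 8.0]}, index=idx)
    return FeatureTable(values=values, labels=labels, covariates=covs)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (102 samples, 150 features) with its truth."""
    return generate_cohort(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort for fast pipeline tests: 60 samples, 30 features."""
    config = SyntheticConfig(
        n_cancer=34, n_control=26, n_features=30, n_rare=5, n_common=5, seed=7
    )
    return generate_cohort(config)
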