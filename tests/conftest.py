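import numpy as np
import pandas as pd
import pytest

from harvestomics import synthetic
from harvestomics.feature_table import FeatureTable


@pytest.fixture(scope="session")
def small_table():
    """Default study design: 4 groups x 3 reps + 4 QC, 200 features."""
    table, truth = synthetic.generate_feature_table(seed=11)
    return table, truth


@pytest.fixture(scope="session")
def driftless_table():
    """No drift, no noise — ground truth is exactly recoverable."""
    table, truth = synthetic.generate_feature_table(
        drift_amplitude=0.0, noise_cv=0.0, seed=5
    )
    return table, truth


@pytest.fixture()
def tiny_table():
    """Hand-built 2-group table with QC rows for unit tests."""
    samples = pd.DataFrame(
        {
            "group": ["A", "A", "B", "B", "QC", "QC", "QC", "QC"],
            "injection_order": [2, 4, 5, 7, 1, 3, 6, 8],
        },
        index=pd.Index([f"s{i}" for i in range(8)], name="sample_id"),
    )
    values = pd.DataFrame(
        {
            "f1": [4.0, 4.0, 8.0, 8.0, 6.0, 6.0, 6.0, 6.0],
            "f2": [10.0, 12.0, 10.0, 12.0, 11.0, 11.0, 11.0, 11.0],
            "f3": [1.0, 1.0, 1.0, 1.0, 1.0, 2.0, 3.0, 4.0],
        },
        index=samples.index,
    )
    return FeatureTable(samples, values)


@pytest.fixture(scope="session")
def odor_table():
    table, truth = synthetic.generate_odor_table(n_compounds=25, n_groups=4, seed=3)
    return table, truth


@pytest.fixture(scope="session")
def separable_data():
    """Two clearly separated groups, 12 samples x 8 features."""
    rng = np.random.default_rng(21)
    X = rng.normal(size=(12, 8))
    X[6:, 0] += 6.0
    X[6:, 1] -= 6.0
    labels = ["A"] * 6 + ["B"] * 6
    return X, labels
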