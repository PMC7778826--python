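import numpy as np
import pandas as pd
import pytest

from psnstack.cohort import CohortConfig, generate_cohort
from psnstack.preprocess import PreprocessPipeline
from psnstack.table import FeatureTable


@pytest.fixture(scope="session")
def small_cohort():
    """~110-record mixed-type cohort with two strong informative features."""
    config = CohortConfig(
        n_couples=80,
        n_numeric=6,
        n_binary=4,
        n_nominal=2,
        n_binominal=1,
        informative_features={0: 1.5, 1: -1.5},
        base_rate=0.35,
        seed=3,
    )
    table, truth = generate_cohort(config)
    return config, table, truth


@pytest.fixture(scope="session")
def processed_cohort(small_cohort):
    _, table, _ = small_cohort
    pipeline = PreprocessPipeline()
    processed = pipeline.fit_transform(table)
    return pipeline, processed


@pytest.fixture()
def numeric_table():
    """Tiny fully numeric table, both classes present."""
    rng = np.random.default_rng(7)
    X = rng.random((40, 3))
    y = (X[:, 0] > 0.5).astype(int)
    return FeatureTable(
        data=pd.DataFrame(X, columns=["a", "b", "c"]),
        outcome=pd.Series(y),
        feature_types={c: "numeric" for c in ["a", "b", "c"]},
    )
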