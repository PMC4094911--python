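import numpy as np
import pandas as pd
import pytest

from morphindex import hierarchical, pipeline
from morphindex.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(n_ad=60, n_ctl=60, n_mci_c=12, n_mci_nc=30, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_train(small_cohort):
    train = pipeline.training_rows(small_cohort.data)
    y = (train["dx"] == "AD").astype(float).to_numpy()
    return train, y


@pytest.fixture(scope="session")
def small_model(small_train):
    train, y = small_train
    cfg = hierarchical.HierarchicalConfig(seed=11)
    return hierarchical.fit_hierarchical(train, y, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
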