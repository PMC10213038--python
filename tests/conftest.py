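import numpy as np
import pytest

from eegpheno.cohort import (
    CohortConfig,
    SubjectTruth,
    default_phenotypes,
    generate_feature_cohort,
)


@pytest.fixture(scope="session")
def phenotypes():
    return default_phenotypes()


@pytest.fixture(scope="session")
def neutral_truth():
    return SubjectTruth("S001", 1, "A", 12.0, "female", 100.0, 80.0, "non", 0.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Feature-level cohort reused across clustering/labeling tests."""
    cfg = CohortConfig(n_subjects=40)
    truths, features, behavior = generate_feature_cohort(cfg, seed=11)
    return truths, features, behavior


@pytest.fixture
def blobs():
    """Two far-separated tight Gaussian blobs in 5 dimensions."""
    rng = np.random.default_rng(3)
    a = rng.normal(0.0, 0.05, size=(20, 5))
    b = rng.normal(0.0, 0.05, size=(20, 5)) + 10.0
    X = np.vstack([a, b])
    labels = np.array([1] * 20 + [2] * 20)
    return X, labels
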