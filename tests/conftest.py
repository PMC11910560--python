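import numpy as np
import pytest

from cheetahbci.preprocess import notch_filter
from cheetahbci.synthetic import CohortSpec, iter_cohort
from cheetahbci.welch import extract_features, features_to_frame


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """Compact cohort: 3 subjects x 4 tasks x 4 trials = 48 trials."""
    return CohortSpec(n_subjects=3, trials_per_task=4, seed=7)


@pytest.fixture(scope="session")
def small_feature_table(small_spec):
    fvs = [extract_features(notch_filter(t)) for t in iter_cohort(small_spec)]
    return features_to_frame(fvs)
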