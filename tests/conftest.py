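import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from bgsleep.decoder import DecodingContext, SearchSpec, evaluate_loso
from bgsleep.synthetic_data import CohortSpec, simulate_feature_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The standard synthetic study: 8 subjects x 600 epochs, 2 channels.

    Shared across decoder-level tests; generated once per session.
    """
    spec = CohortSpec(n_subjects=8, epochs_per_night=600, n_channels=2, seed=0)
    return simulate_feature_cohort(spec)


@pytest.fixture(scope="session")
def default_loso(default_cohort):
    """Leave-one-subject-out results on the standard cohort."""
    return evaluate_loso(
        default_cohort, DecodingContext(), SearchSpec(search_rounds=0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
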