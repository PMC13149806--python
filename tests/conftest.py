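import numpy as np
import pandas as pd
import pytest

from driftspread.config import CohortConfig
from driftspread.cohort import generate_cohort
from driftspread.derive import compute_trial_differences, fit_attribute_weights


@pytest.fixture(scope="session")
def small_cohort():
    """12 participants x 40 options: enough structure for unit tests."""
    cfg = CohortConfig(n_participants=12, n_options=40, seed=42)
    ratings, pairings, true_params, meta = generate_cohort(cfg)
    return cfg, ratings, pairings, true_params, meta


@pytest.fixture(scope="session")
def derived_trials(small_cohort):
    _, ratings, pairings, _, _ = small_cohort
    weights = fit_attribute_weights(ratings)
    return weights, compute_trial_differences(ratings, pairings, weights)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
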