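import numpy as np
import pandas as pd
import pytest

from pwvrec.cohort import generate_cohort
from pwvrec.preprocess import build_arm_datasets, filter_eligible


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-patient cohort at the default noise level, with its truth."""
    cohort, truth = generate_cohort(400, seed=42)
    return cohort, truth


@pytest.fixture(scope="session")
def noiseless_cohort():
    """A 600-patient noiseless cohort: observed change equals g_d exactly."""
    cohort, truth = generate_cohort(600, seed=7, noise_sd=0.0)
    return cohort, truth


@pytest.fixture(scope="session")
def small_arm_datasets(small_cohort):
    cohort, _ = small_cohort
    datasets, params = build_arm_datasets(filter_eligible(cohort))
    return datasets, params


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
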