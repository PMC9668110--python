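from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import normadapt as na

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def default_task() -> na.TaskConfig:
    return na.default_task()


@pytest.fixture(scope="session")
def small_cohort():
    """Five simulated RW_fixed responders with ground truth (shared, read-only)."""
    trials, truth = na.simulate_cohort(na.CohortSpec(n_participants=5, seed=3))
    return trials, truth


@pytest.fixture(scope="session")
def small_cohort_fits(small_cohort):
    """All six models fitted to the five shared responders."""
    trials, _ = small_cohort
    return na.fit_cohort(trials, na.MODEL_IDS, na.OptimizerConfig(seed=1))


@pytest.fixture(scope="session")
def medium_cohort():
    """A study-sized cohort (30 x 60 trials) for behavioral statistics."""
    trials, truth = na.simulate_cohort(na.CohortSpec(n_participants=30, seed=7))
    return trials, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
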