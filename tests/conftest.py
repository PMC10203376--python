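import numpy as np
import pytest

from longidistill.longio import LongitudinalCohort
from longidistill.synthgen import SynthConfig, generate_cohort

# the published worked example: one subject observed at weeks 0 and 52 on the
# (0, 4, 12, 52) grid, leading/trailing family abundances as printed
WEEK0_ROW = np.array([0.29747, 0.00381, 0.00114, 0.18839])
WEEK52_ROW = np.array([0.00168, 0.00839, 0.00839, 0.50269])
WEEK_GRID = [0, 4, 12, 52]


@pytest.fixture
def week_subject_cohort():
    return LongitudinalCohort(
        subject_ids=["P1"],
        sequences=[[(0, WEEK0_ROW), (52, WEEK52_ROW)]],
        labels=["moderate"],
        canonical_grid=WEEK_GRID,
        n_features=4,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """60 subjects, 12 taxa, strong signal — enough for fast training tests."""
    cohort, _ = generate_cohort(SynthConfig(
        n_subjects=60, n_features=12, n_timepoints=4, effect_size=0.8,
        missing_rate=0.2, seed=11))
    return cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
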