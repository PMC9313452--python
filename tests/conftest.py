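import numpy as np
import pytest

import sesimclr as s


@pytest.fixture(scope="session")
def small_cohort():
    """An 11-subject cohort (6 math / 5 non-math), study-shaped but desk-sized."""
    return s.generate_cohort(s.CohortConfig(n_math=6, n_nonmath=5, seed=7))


@pytest.fixture(scope="session")
def small_slices(small_cohort):
    return s.cohort_to_slices(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
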