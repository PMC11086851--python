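import numpy as np
import pytest

from spineflex.pipeline import cohort_design_matrices
from spineflex.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-condition cohort: 41 MI / 42 MCI, fixed seed."""
    cohort = generate_cohort(CohortSpec(seed=7))
    angle_X, proms_X, y, pids = cohort_design_matrices(cohort)
    return cohort, angle_X, proms_X, y


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Small cohort without pixel noise, for parameter-recovery oracles."""
    spec = CohortSpec(n_mi=6, n_mci=6, pixel_noise_sd=0.0, seed=11)
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
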