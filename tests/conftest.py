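import numpy as np
import pytest

from nlfnc import CohortSpec, default_cohort_spec, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-group cohort with 2 purely nonlinear group-difference pairs."""
    spec = default_cohort_spec(n_subjects_per_group=12, seed=99, n_nonlinear_pairs=2)
    return spec, simulate_cohort(spec)


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no group differences (group_delta empty)."""
    spec = CohortSpec(
        n_subjects_per_group=12,
        n_components=6,
        linear_coupling={(0, 1): 0.4, (2, 3): 0.4},
        seed=7,
        domain_assignment=("D1", "D1", "D1", "D2", "D2", "D2"),
    )
    return spec, simulate_cohort(spec)
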