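import numpy as np
import pytest

from funconn import SyntheticCohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_spec():
    """Small but structurally faithful cohort spec for fast tests."""
    return SyntheticCohortSpec(
        group_sizes={"HC": 3, "PD_nICD": 4, "PD_ICD": 4},
        n_rois=40,
        n_volumes=120,
        seed=1234,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
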