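import numpy as np
import pytest

from mciagaspp.data_io import subject_split
from mciagaspp.phantom import PhantomSpec, generate_cohort

TINY_GRID = (16, 20, 16)


@pytest.fixture(scope="session")
def tiny_spec():
    """Small but class-separable phantom spec used across tests."""
    return PhantomSpec(
        grid_shape=TINY_GRID,
        n_subjects_per_class=4,
        scans_per_subject=2,
        atrophy_factor=0.6,
        noise_sd=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec, tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny_cohort")
    return generate_cohort(tiny_spec, out)


@pytest.fixture(scope="session")
def tiny_split(tiny_cohort):
    return subject_split(tiny_cohort, test_fraction=0.25, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
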