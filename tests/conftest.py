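import numpy as np
import pytest

from connparc.phantom import (PhantomSpec, CohortSpec, default_phantom_spec,
                              make_phantom_subject)


@pytest.fixture(scope="session")
def small_spec():
    """A fast phantom: 4 parcels, short series."""
    return PhantomSpec(grid_shape=(10, 10, 6), n_parcels=4, n_timepoints=120,
                       signal_corr=0.7, noise_sd=0.5, seed=42)


@pytest.fixture(scope="session")
def small_subject(small_spec):
    return make_phantom_subject(small_spec, subject_seed=1)


@pytest.fixture(scope="session")
def noisefree_subject():
    spec = default_phantom_spec(noise_sd=0.0, signal_corr=0.8,
                                n_timepoints=150, seed=5)
    return spec, make_phantom_subject(spec, subject_seed=2)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    from connparc.phantom import make_cohort
    spec = CohortSpec(n_per_group=4, phantom=small_spec)
    return spec, make_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
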