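import numpy as np
import pytest
from hypothesis import settings

import relaxnorm as rn

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_spec():
    """24^3 phantom grid: big enough for a nonempty WM mask, cheap to fit."""
    return rn.PhantomSpec(grid_shape=(24, 24, 24), seed=7)


@pytest.fixture(scope="session")
def small_labels(small_spec):
    return rn.generate_tissue_labels(small_spec)


@pytest.fixture(scope="session")
def control_cohort(small_spec):
    """Eight lesion-free controls on the small grid."""
    return rn.generate_cohort(small_spec, n_controls=8, n_welders=0)


@pytest.fixture(scope="session")
def small_atlas(control_cohort):
    mask = rn.build_wm_mask(control_cohort.tissue_probability_maps)
    ages = [r.age for r in control_cohort.records]
    return rn.fit_atlas(control_cohort.volumes, ages, mask)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
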