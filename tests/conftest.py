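import numpy as np
import pytest

from zfsleep import reference_wt_params
from zfsleep.simulate import generate_cohort, preset


@pytest.fixture(scope="session")
def wt_gen():
    """Homogeneous 4-state wild-type generator (reference rates/transitions)."""
    return reference_wt_params()


@pytest.fixture(scope="session")
def wt_cohort():
    """Small circadian wild-type cohort with ground truth (8 fish x 48 h)."""
    return generate_cohort(preset("wt"), n_fish=8, duration_h=48.0, seed=101)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
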