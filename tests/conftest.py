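import numpy as np
import pytest

from ratesync import psychometric as psy
from ratesync import synthetic_data as synth


@pytest.fixture(scope="session")
def small_cohort():
    """10-participant cohort with an increase truth, for model-level tests."""
    spec = synth.GenerativeSpec(seed=2, n_high=6, n_low=4)
    return synth.draw_threshold_dataset(spec)


@pytest.fixture(scope="session")
def study_cohort():
    """Full-size cohort (35 high / 20 low) at the default generative truth."""
    return synth.draw_threshold_dataset(synth.GenerativeSpec(seed=3))


@pytest.fixture()
def observer():
    return synth.make_observer(0.05, 0.05, 0.02)


@pytest.fixture()
def cs_design():
    return psy.CSDesign(standard_rate=4.0,
                        levels=tuple(psy.comparison_levels(0.05)))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
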