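import numpy as np
import pytest

from chokelab import CohortConfig, Participant, generate_cohort
from chokelab.config import EffectConfig


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-participant cohort with enough trials for complete cells."""
    config = CohortConfig(n_participants=6, trials_per_cell=8)
    participants, trials = generate_cohort(config, seed=11)
    return config, participants, trials


@pytest.fixture
def participant():
    return Participant(id="P01", loss_aversion=2.0, base_skill=0.8,
                       choke_depth=0.15, facilitation=0.1)


@pytest.fixture
def effect():
    return EffectConfig(reappraisal_attenuation=0.25)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
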