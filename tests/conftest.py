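import numpy as np
import pytest

import audiotactile as at
from audiotactile.pipeline import analyze_session


@pytest.fixture(scope="session")
def mixed_session():
    """A small synthetic session with every cell type represented."""
    pop = at.sample_population(
        {"touch_low_btf": 0.15, "touch_high_btf": 0.3, "sound_TI": 0.1,
         "sound_NTI": 0.1, "both": 0.05},
        n_neurons=30, seed=2)
    sched = at.make_stimulus_schedule(["tactile", "auditory", "combined"],
                                      n_repeats=6, seed=1)
    return at.synthesize_session(pop, sched, seed=3)


@pytest.fixture(scope="session")
def mixed_analysis(mixed_session):
    return analyze_session(mixed_session)


@pytest.fixture(scope="session")
def ladder():
    return at.frequency_ladder()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
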