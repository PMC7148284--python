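import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """2 participants x 1 block x 3 reps/cell (48 trials/participant)."""
    from joyddm.cohort import synth_cohort

    design, trials, pp = synth_cohort(n_participants=2, seed=7, n_blocks=1, reps_per_cell=3)
    return design, trials, pp
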