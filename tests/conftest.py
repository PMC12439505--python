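import numpy as np
import pytest

from pergdwt import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def default_params():
    return synthetic.WaveformParams()


@pytest.fixture(scope="session")
def small_cohort():
    """12 participants, 2 recordings each, fixed seed."""
    config = synthetic.CohortConfig(
        n_normal=6, n_mpird=6, recordings_per_participant=2, seed=7
    )
    return synthetic.generate_cohort(config)
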