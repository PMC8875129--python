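import hypothesis
import numpy as np
import pytest

from cacoflux import DEFAULT_SCHEDULE, efflux_params, passive_params

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def schedule():
    return DEFAULT_SCHEDULE


@pytest.fixture(scope="session")
def passive():
    """Noiseless purely passive compound, sink-regime permeability."""
    return passive_params(p_passive=1e-6)


@pytest.fixture(scope="session")
def efflux():
    """Noiseless efflux substrate giving ER near 3 at c0=100 ug/mL."""
    return efflux_params()


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
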