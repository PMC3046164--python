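import numpy as np
import pytest

from numotion import DisplayGeometry, ObserverParams, simulate_estimates


@pytest.fixture(scope="session")
def geometry():
    return DisplayGeometry()


@pytest.fixture(scope="session")
def default_table():
    """One simulated 11-subject session at the default design."""
    return simulate_estimates(range(10, 31), subjects=11, reps=6,
                              params=ObserverParams(), seed=1234)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
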