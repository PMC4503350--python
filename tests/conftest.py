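import pytest

from tumorca import CscConfig, Params, initialize, seed_cscs


@pytest.fixture
def params():
    return Params()


@pytest.fixture
def no_death_params():
    """All stochastic death channels off, mutations off."""
    return Params(m=float("inf"), a=float("inf"))


@pytest.fixture
def small_state():
    """A full 8-cube of healthy cells, deterministic seed."""
    return initialize(8, Params(), seed=42)


@pytest.fixture(scope="session")
def full_grid_state():
    """The published grid size (50 per dimension) with 1% stem cells seeded.

    Session-scoped because construction is the expensive part; tests must not
    mutate it.
    """
    state = initialize(50, Params(), seed=7)
    seed_cscs(state, CscConfig(fraction=0.01))
    return state
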