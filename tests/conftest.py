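import numpy as np
import pytest

import lbaction as lba


@pytest.fixture(scope="session")
def designs():
    return lba.enumerate_designs()


@pytest.fixture(scope="session")
def design_base(designs):
    return designs[0]


@pytest.fixture(scope="session")
def design_rate(designs):
    """The repetition-only rate-modulation design (index 4)."""
    return designs[3]


@pytest.fixture(scope="session")
def group_params():
    return lba.default_group_params()


@pytest.fixture(scope="session")
def rate_mods():
    return [lba.default_modulations(beta_choice=0.7)]


@pytest.fixture(scope="session")
def small_session():
    """A reduced session (252 trials) for fast behavioural tests."""
    spec = lba.SessionSpec(n_trials=252)
    return lba.generate_session(spec, seed=11)


@pytest.fixture(scope="session")
def small_trials(small_session, group_params, rate_mods, design_rate):
    return lba.generate_behavior(
        small_session, group_params, rate_mods, design_rate, seed=12
    )


@pytest.fixture(scope="session")
def full_trials(group_params, rate_mods, design_rate):
    """One full 1008-trial synthetic participant (true beta_choice = 0.7)."""
    session = lba.generate_session(lba.SessionSpec(), seed=21)
    return lba.generate_behavior(session, group_params, rate_mods, design_rate, seed=22)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_fit_config():
    """Deliberately small configuration for fit smoke tests."""
    return lba.FitConfig(
        n_sim=2000, n_restarts=1, n_candidates=20, max_iter=40, n_polish=0
    )
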