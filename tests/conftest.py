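import numpy as np
import pytest

from cerebsim import (
    scenario_locomotion,
    scenario_wr,
    scenario_wr_suspension,
)


@pytest.fixture(scope="session")
def wr_contextualised_offset():
    """Whisking-respiration run with the all-ones pf pattern under an
    intrinsic angular-velocity offset."""
    return scenario_wr("offset", contextualise=True, seed=1)


@pytest.fixture(scope="session")
def wr_naive_offset_noise():
    """Identity-pf run (no coordination expectations) under offset plus
    phase noise."""
    return scenario_wr("offset_noise", contextualise=False, seed=1)


@pytest.fixture(scope="session")
def wr_perturbed():
    return scenario_wr("perturbation", contextualise=True, seed=1)


@pytest.fixture(scope="session")
def wr_suspension():
    """Offset+noise run with CN output suspended for the final stretch."""
    return scenario_wr_suspension(seed=1)


@pytest.fixture(scope="session")
def loco_contextualised():
    return scenario_locomotion(contextualise=True, seed=1)


@pytest.fixture(scope="session")
def loco_naive():
    return scenario_locomotion(contextualise=False, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
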