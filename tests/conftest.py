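"""Shared fixtures: small synthetic sessions reused across test modules."""

import numpy as np
import pytest

from placecode.synth import CONTROL, generate_trajectory, simulate_session


@pytest.fixture(scope="session")
def short_bundle():
    """Control session with a 300 s exploration and 240 s sleep."""
    plan = (("familiar_explore", 300.0), ("sleep_familiar", 240.0))
    return simulate_session(CONTROL, seed=42, n_pyr=20, n_int=4, epoch_plan=plan)


@pytest.fixture(scope="session")
def foraging_tracking():
    """20 min default foraging trajectory."""
    return generate_trajectory(1200.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
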