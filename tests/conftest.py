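import dataclasses

import numpy as np
import pytest

from tugseg import TugScenario, simulate


@pytest.fixture(scope="session")
def default_recording():
    """Default synthetic TUG recording with its ground truth (seeded)."""
    return simulate(TugScenario(seed=42))


@pytest.fixture(scope="session")
def noiseless_recording():
    scn = TugScenario(seed=42, noise_sd_angle=0.0, noise_sd_acc=0.0,
                      noise_sd_gyr=0.0)
    return simulate(scn)


@pytest.fixture
def make_scenario():
    """Factory for scenario variants of the default parameters."""
    def _make(**overrides):
        return dataclasses.replace(TugScenario(), **overrides)
    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
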