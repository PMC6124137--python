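import numpy as np
import pytest
from hypothesis import settings

from fightkit.core import ArenaConfig, Ethogram, FightRecording
from fightkit.simulate import SimulationConfig, simulate_fight

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def arena():
    return ArenaConfig()


@pytest.fixture(scope="session")
def short_fight():
    """A 2-minute simulated fight with attacks in both fight phases."""
    cfg = SimulationConfig(
        duration_s=120.0, seed=3,
        phases=((0.0, 30.0, "pre-fight"), (30.0, 70.0, "symmetric"),
                (70.0, 120.0, "asymmetric")),
        attack_rate_per_min=10.0)
    return simulate_fight(cfg)


@pytest.fixture(scope="session")
def short_recording(short_fight):
    return short_fight[0]


@pytest.fixture(scope="session")
def short_truth(short_fight):
    return short_fight[1]


@pytest.fixture(scope="session")
def short_ethogram(short_truth):
    return Ethogram.from_labels(short_truth.labels, short_truth.role)


def make_recording(positions, arena=None):
    """Helper: wrap a (T, 2, 2) array in a FightRecording."""
    return FightRecording(np.asarray(positions, float),
                          arena or ArenaConfig())
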