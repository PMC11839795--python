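import numpy as np
import pytest

from qpath import QLearningConfig, RiskVolume


@pytest.fixture
def fast_config():
    """A planner config sized for tiny toy grids."""
    return QLearningConfig(episodes_max=400, stable_episodes=30, seed=7)


@pytest.fixture
def zero_risk_5():
    return RiskVolume(np.zeros((5, 5, 5)), (1.0, 1.0, 1.0))


def random_risk_volume(rng, max_dim=15, spacing=(0.8, 0.8, 0.8),
                       levels=(0.0, 0.3, 0.7, 1.0), p=(0.4, 0.25, 0.2, 0.15)):
    """A random mixed-risk phantom field of the kind the planner is validated on."""
    dims = tuple(int(rng.integers(8, max_dim + 1)) for _ in range(3))
    risk = rng.choice(levels, size=dims, p=p)
    return RiskVolume(risk, spacing)
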