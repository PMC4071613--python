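import numpy as np
import pytest

from neurogait.engine import EpisodeConfig, run_episode
from neurogait.muscle import DEFAULT_MUSCLES
from neurogait.reflex import build_default_pathways
from neurogait.synthetic import make_synthetic_gait


@pytest.fixture(scope="session")
def pathways():
    return build_default_pathways()


@pytest.fixture(scope="session")
def sol():
    return DEFAULT_MUSCLES[3]


@pytest.fixture(scope="session")
def synthetic_gait():
    """50 quasi-periodic cycles with 2% jitter/noise, fixed seed."""
    return make_synthetic_gait(period=1.0, jitter=0.02, noise=0.02,
                               n_cycles=50, seed=7)


@pytest.fixture(scope="session")
def short_episode_log():
    """One short feedback-driven episode on flat ground, reused by the
    logging/clamp assertions."""
    cfg = EpisodeConfig(duration=1.5)
    return run_episode(cfg)
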