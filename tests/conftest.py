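import numpy as np
import pytest

from adaptimu import pipeline


@pytest.fixture(scope="session")
def trained_system():
    """Small trained system shared by runtime and acceptance tests.

    Six simulated athletes, 60 s each, injuries at 4/min; branch training
    kept to a few epochs and three replay passes for the agent.
    """
    cfg = pipeline.SystemConfig(
        sim=pipeline.SimulationConfig(n_subjects=6, session_s=60.0,
                                      injury_rate=4.0, seed=1),
        cnn_epochs=4, lstm_epochs=4, finetune_epochs=1, rl_passes=3, seed=1)
    return pipeline.train_system(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
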