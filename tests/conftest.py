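import numpy as np
import pytest

from sonarseg.model import CrfSegmenter
from sonarseg.synthetic import make_environment, simulate_scene
from sonarseg.training import TrainingConfig, fit
from sonarseg.unary import UnaryConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_unary_config(num_labels=2, dropout=0.0):
    return UnaryConfig(
        in_channels=3, num_labels=num_labels, block_width=4,
        convs_per_block=1, head_width=8, dropout=dropout,
    )


@pytest.fixture
def tiny_model():
    """Untrained small binary segmenter."""
    return CrfSegmenter(small_unary_config(), mf_iterations=3, sim_hidden=4, seed=0)


@pytest.fixture(scope="session")
def training_scenes():
    """Small, well-contrasted scenes for trainer and similarity tests."""
    env = make_environment("A")
    return [
        simulate_scene(
            env, n_fish=3, seed=100 + i, shape=(32, 32),
            axes_range=((3.0, 4.5), (1.5, 2.5)), speed_range=(1.0, 2.0),
        )
        for i in range(4)
    ]


@pytest.fixture(scope="session")
def trained_binary(training_scenes):
    """A binary segmenter trained briefly on env-A scenes (shared: training
    is the slow part of the suite)."""
    cfg = UnaryConfig(
        in_channels=3, num_labels=2, block_width=8,
        convs_per_block=1, head_width=16, dropout=0.0,
    )
    model = CrfSegmenter(cfg, mf_iterations=3, sim_hidden=8, seed=1)
    dataset = [(s.stack(), s.annotation) for s in training_scenes]
    tcfg = TrainingConfig(learning_rate=0.2, momentum=0.9, batch_size=2,
                          epochs=25, seed=7)
    model, history = fit(model, dataset, tcfg)
    return model, history, dataset
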