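import numpy as np
import pytest

from somnoring.core import EpochGrid, Hypnogram
from somnoring.simulate import SimConfig, simulate_night


@pytest.fixture(scope="session")
def short_night():
    """One 1-hour synthetic night with temperature artifacts enabled."""
    cfg = SimConfig(seed=5, night_duration_h=1.0, temp_artifact_rate=0.01)
    return simulate_night(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_hypnogram(stages, vocab="four"):
    stages = np.asarray(stages, dtype=object)
    return Hypnogram(EpochGrid(n_epochs=len(stages)), stages, vocab=vocab)
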