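"""Shared fixtures: small synthetic datasets and a tiny trained model.

Everything is generated at test time from seeds; session scope keeps the
expensive pieces (recordings, a short training run) shared across tests.
"""

import numpy as np
import pytest

from bowelwarn import preprocess, synth, train


@pytest.fixture(scope="session")
def default_config():
    return synth.SynthConfig()


@pytest.fixture(scope="session")
def separable_config():
    return synth.SynthConfig.separable()


@pytest.fixture(scope="session")
def small_recordings(separable_config):
    """Four recordings per class, 60 s each (96 segments total)."""
    return [synth.generate_recording(separable_config, label, 100 * label + i)
            for label in (0, 1) for i in range(4)]


@pytest.fixture(scope="session")
def random_frames():
    """40 random frames in [-1, 1] with balanced labels — valid network
    inputs without any acoustic structure (for mechanics-only tests)."""
    rng = np.random.default_rng(42)
    frames = rng.uniform(-1, 1, (40, preprocess.WINDOW)).astype(np.float32)
    labels = np.array([0, 1] * 20, dtype=np.int64)
    return frames, labels


@pytest.fixture(scope="session")
def tiny_train_result(random_frames):
    """A 2-epoch SSGAN run on the random frames (mechanics, not skill)."""
    frames, labels = random_frames
    config = train.TrainConfig(epochs=2, seed=7, noise_length=32)
    return train.train(frames[:30], labels[:30], frames[30:], config), config
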