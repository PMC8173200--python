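import numpy as np
import pandas as pd
import pytest

from dundun.audio_io import AudioRecording, compute_frame_features
from dundun.synthetic import CorpusConfig, ListenerConfig, make_corpus, simulate_listeners, synthetic_stimulus_features

RATE = 22050.0


def harmonic_tone(f0, duration_s=1.5, rate=RATE, partials=(1.0, 0.4, 0.15)):
    t = np.arange(int(duration_s * rate)) / rate
    x = sum(a * np.sin(2 * np.pi * (k + 1) * f0 * t) for k, a in enumerate(partials))
    return AudioRecording(np.asarray(x), rate, f"tone{f0:g}")


@pytest.fixture(scope="session")
def sine220():
    return harmonic_tone(220.0, partials=(1.0,))


@pytest.fixture(scope="session")
def sine220_frames(sine220):
    return compute_frame_features(sine220)


@pytest.fixture(scope="session")
def small_corpus():
    """4 music + 4 speech stimuli, short durations: shared by several suites."""
    cfg = CorpusConfig(n_music=4, n_speech=4, duration_s=(5.0, 6.5), seed=1)
    return make_corpus(cfg)


@pytest.fixture(scope="session")
def stimulus_features():
    return synthetic_stimulus_features(seed=2)


@pytest.fixture(scope="session")
def listener_responses(stimulus_features):
    cfg = ListenerConfig(n_familiar=25, n_unfamiliar=25, seed=4)
    return simulate_listeners(cfg, stimulus_features)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
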