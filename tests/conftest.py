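import numpy as np
import pytest

from callrec import RecognizerSettings, SceneConfig, synth_scene


@pytest.fixture(scope="session")
def default_settings():
    return RecognizerSettings()


@pytest.fixture(scope="session")
def small_scene():
    """Four 30-s recordings at train-like SNR with ~20 calls total."""
    cfg = SceneConfig(
        n_sites=2,
        recordings_per_site=2,
        duration_s=30.0,
        calls_per_recording=5.0,
        snr_db=13.0,
        seed=1,
    )
    recordings, annotations = synth_scene(cfg, 1)
    return cfg, recordings, annotations


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
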