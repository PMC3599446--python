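import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import songseg as ss
from songseg.pipeline import segment

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def synth60():
    """A 60 s default-condition synthetic song with ground truth."""
    cfg = ss.SynthConfig(duration_s=60.0, seed=1)
    rec, truth, events = ss.generate(cfg)
    return cfg, rec, truth, events


@pytest.fixture(scope="session")
def seg60(synth60):
    """Full segmentation of the 60 s synthetic song (shared; ~5 s)."""
    _, rec, _, _ = synth60
    return segment(rec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def noise_recording(rng, duration_s=10.0, sd=0.05, fs=10_000):
    return ss.Recording(rng.normal(0, sd, int(duration_s * fs)), fs)
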