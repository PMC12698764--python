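import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def background_60s():
    """60 s two-channel 1/f background at 128 Hz."""
    from weareeg import synth

    return synth.gen_background(synth.SynthSpec(fs=128.0, duration_s=60.0,
                                                seed=7))


@pytest.fixture(scope="session")
def small_corpus():
    """Scaled-down seizure corpus: 10 records x 10 min at 128 Hz,
    12 seizures total, for fast end-to-end tests."""
    from weareeg import synth

    return synth.default_seizure_dataset(seed=1, n_records=10,
                                         record_s=600.0, fs=128.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
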