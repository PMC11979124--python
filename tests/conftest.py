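import numpy as np
import pytest
from hypothesis import settings

import respiradar as rr
from respiradar.pipeline import ChannelSignal

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def noisy_config():
    """Acquisition config with moderate channel noise (5% of amplitude)."""
    return rr.RadarConfig(noise_sd=0.05)


@pytest.fixture
def clean_config():
    """Noise-free, quantization-free acquisition config."""
    return rr.RadarConfig(noise_sd=0.0, adc_bits=0)


def steady_scenario(rate_bpm, duration=60.0, jitter=0.0, seed=0, **kw):
    return rr.RespirationScenario(
        segments=((float(duration), float(rate_bpm)),),
        rate_jitter_sd=jitter,
        seed=seed,
        **kw,
    )


def reference_channel(ref: rr.ReferenceTrace) -> ChannelSignal:
    return ChannelSignal(times=ref.times, values=ref.displacement, kind="R")


@pytest.fixture
def steady60_recording(noisy_config):
    sc = steady_scenario(60.0, duration=60.0, jitter=2.0, seed=11)
    return rr.simulate_recording(sc, noisy_config)
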