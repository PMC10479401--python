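import numpy as np
import pytest

from hcloop.ephys import StimulusEvent, Sweep
from hcloop.synth import SynthConfig


@pytest.fixture
def cfg() -> SynthConfig:
    return SynthConfig(seed=1234)


@pytest.fixture
def quiet_cfg() -> SynthConfig:
    """Noise-free generator configuration for exact round-trips."""
    return SynthConfig(seed=1234, noise_sd=0.0, image_noise_sd=0.0)


def make_flat_sweep(level=-70.0, n=10_000, onset=0.15, clamp_mode="current",
                    duration=0.002, modality="optical"):
    return Sweep(
        samples=np.full(n, float(level)),
        stimulus=StimulusEvent(onset=onset, duration=duration, modality=modality),
        clamp_mode=clamp_mode,
        holding=level if clamp_mode == "current" else -80.0,
    )
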