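import numpy as np
import pytest

from vbreath.signal_model import (
    Axis,
    ChannelRecording,
    Device,
    GaitSample,
    Sensor,
    Session,
    all_channel_keys,
)
from vbreath.simulate import SimConfig, simulate_cohort, simulate_subject


def make_recording(
    device=Device.WRIST,
    sensor=Sensor.ACCELEROMETER,
    axis=Axis.X,
    rate=62.0,
    duration_s=16.0,
    signal=None,
    seed=0,
):
    """A uniform-rate recording; default content is a 1.8 Hz walk-like tone."""
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    if signal is None:
        rng = np.random.default_rng(seed)
        signal = 2.0 * np.sin(2 * np.pi * 1.8 * t) + rng.normal(0, 0.3, n)
    return ChannelRecording(
        device=device,
        sensor=sensor,
        axis=axis,
        timestamps=np.round(t * 1e9).astype(np.int64),
        values=np.asarray(signal, dtype=float),
        nominal_rate=rate,
    )


def make_sample(subject_id="S001", session=Session.BEFORE, brac=0.0, seed=0):
    """A valid 16 s GaitSample with walk-like content in all 12 channels."""
    channels = {}
    for i, (d, s, a) in enumerate(all_channel_keys()):
        rate = 180.0 if d is Device.SMARTPHONE else 62.0
        channels[(d, s, a)] = make_recording(d, s, a, rate=rate, seed=seed * 100 + i)
    return GaitSample(subject_id=subject_id, session=session, channels=channels, brac=brac)


@pytest.fixture(scope="session")
def strong_cohort():
    """A 30-subject cohort with a strong dose effect, shared across tests."""
    return simulate_cohort(SimConfig(n_subjects=30, effect_size=3.0, seed=7))


@pytest.fixture(scope="session")
def one_pair():
    rng = np.random.default_rng(np.random.SeedSequence(11))
    return simulate_subject(SimConfig(effect_size=3.0), rng, subject_id="S001")
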