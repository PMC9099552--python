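"""Synthetic paired free-gait cohort with a dose-dependent intoxication transform.

Each subject walks twice for 16 seconds: once sober (the baseline) and once
after drinking.  A session's channels are periodic-gait signals — a step
fundamental near 1.8 Hz plus two harmonics, a slow postural-sway component,
and Gaussian sensor noise — sampled at each device's native rate with
nanosecond timestamps.  The after-session BrAC is drawn from a mixture of a
point mass at zero (abstainers) and a lognormal over drinkers, calibrated
so the expected intoxicated fractions are ≈1/3 at a 220 threshold, ≈0.30 at
240 and ≈0.10 at 380 µg/L.

Intoxication enters through four effect channels, each scaled by the dose
``effect_size · min(brac, 320) / 240`` (so the 240-threshold task has unit
effect at its decision boundary, and impairment plateaus at severe
intoxication):

* cadence slows (reduced frequency of movement),
* harmonic amplitude shrinks (decreased average acceleration),
* low-frequency sway power grows (balance difficulty), with stronger
  coupling on the wrist than on the pocket-carried phone (arm swing),
* sensor-level noise grows (irregular gait).

The generator claims qualitative, not physiological, fidelity: it gives the
pipeline a cohort whose separability is controlled by a single knob.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .signal_model import (
    Axis,
    ChannelKey,
    ChannelRecording,
    Device,
    GaitSample,
    Sensor,
    Session,
    SubjectPair,
    all_channel_keys,
    write_session,
    NS_PER_S,
)

__all__ = ["SimConfig", "simulate_subject", "simulate_cohort", "write_cohort"]

#: Baseline oscillation amplitude per sensor (m/s² for the accelerometer,
#: rad/s for the gyroscope) — typical free-walking magnitudes.
_BASE_AMP = {Sensor.ACCELEROMETER: 2.5, Sensor.GYROSCOPE: 1.2}

#: Fixed gait anisotropy: the vertical/fore-aft axis carries more power
#: than the lateral ones.  The profile is device/sensor/axis-specific and
#: identical across subjects; individual gait style enters through cadence.
_AXIS_WEIGHT = {Axis.X: 1.0, Axis.Y: 0.8, Axis.Z: 0.6}

#: Per-unit-dose effect magnitudes.  The amplitude and sway effects are
#: sized so that one dose unit shifts the signal by one channel-noise sigma
#: at the reference accelerometer amplitude (0.12 x 2.5 = 0.3 m/s^2), i.e.
#: effect_size reads directly in noise-sigma units.
_CADENCE_DROP = 0.04      # fractional cadence reduction
_AMP_DROP = 0.12          # fractional amplitude damping
_SWAY_GAIN = 0.12         # sway amplitude added, as a fraction of channel amplitude
_NOISE_GAIN = 0.10        # fractional noise-sigma inflation
_WRIST_SWAY_FACTOR = 1.5  # arm swing couples sway more strongly into the wrist

#: Gait impairment plateaus at severe intoxication: effects scale with
#: min(brac, _BRAC_SATURATION)/240, so readings beyond ~1.33x the 240
#: boundary all produce the same (maximal) gait change.
_BRAC_SATURATION = 320.0


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for the synthetic cohort."""

    n_subjects: int = 30
    duration_s: float = 16.0
    rates: Mapping[Device, float] = field(
        default_factory=lambda: {Device.SMARTPHONE: 180.0, Device.WRIST: 62.0}
    )
    cadence_hz: float = 1.8
    cadence_jitter: float = 0.15
    harmonic_amps: tuple[float, float, float] = (1.0, 0.5, 0.25)
    noise_sigma: float = 0.3
    sway_freq_hz: float = 0.5
    effect_size: float = 1.0
    #: P(subject drinks); abstainers blow a BrAC of 0.
    p_drinker: float = 0.4325
    #: Lognormal parameters of a drinker's BrAC (µg/L breath); together with
    #: p_drinker these put ≈1/3, 0.30, 0.10 of subjects above 220/240/380.
    brac_log_mu: float = 5.6681
    brac_log_sigma: float = 0.3703
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.duration_s < 14.0:
            raise ValueError("duration_s must cover the 14 s analysis window end")
        if any(r <= 0 for r in self.rates.values()):
            raise ValueError("sampling rates must be positive")
        for name in ("cadence_hz", "sway_freq_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("cadence_jitter", "noise_sigma", "effect_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if any(a < 0 for a in self.harmonic_amps):
            raise ValueError("harmonic amplitudes must be non-negative")
        if not 0.0 <= self.p_drinker <= 1.0:
            raise ValueError("p_drinker must lie in [0, 1]")


def _draw_brac(config: SimConfig, rng: np.random.Generator) -> float:
    if rng.random() >= config.p_drinker:
        return 0.0
    return float(rng.lognormal(config.brac_log_mu, config.brac_log_sigma))


def _session_channels(
    config: SimConfig,
    rng: np.random.Generator,
    cadence: float,
    dose: float,
) -> dict[ChannelKey, ChannelRecording]:
    cadence_eff = max(0.5, cadence * (1.0 - _CADENCE_DROP * dose))
    amp_scale = max(0.3, 1.0 - _AMP_DROP * dose)
    noise_scale = 1.0 + _NOISE_GAIN * dose
    channels: dict[ChannelKey, ChannelRecording] = {}
    for key in all_channel_keys():
        device, sensor, axis = key
        rate = config.rates[device]
        n = int(round(config.duration_s * rate))
        t = np.arange(n) / rate
        amp = _BASE_AMP[sensor] * _AXIS_WEIGHT[axis]
        signal = np.zeros(n)
        for h, h_amp in enumerate(config.harmonic_amps, start=1):
            phase = rng.uniform(0, 2 * math.pi)
            signal += amp * amp_scale * h_amp * np.sin(
                2 * math.pi * h * cadence_eff * t + phase
            )
        sway_amp = amp * (
            0.05 + _SWAY_GAIN * dose * (_WRIST_SWAY_FACTOR if device is Device.WRIST else 1.0)
        )
        signal += sway_amp * np.sin(2 * math.pi * config.sway_freq_hz * t + rng.uniform(0, 2 * math.pi))
        signal += rng.normal(0.0, config.noise_sigma * noise_scale, n)
        timestamps = np.round(t * NS_PER_S).astype(np.int64)
        channels[key] = ChannelRecording(
            device=device,
            sensor=sensor,
            axis=key[2],
            timestamps=timestamps,
            values=signal,
            nominal_rate=rate,
        )
    return channels


def simulate_subject(
    config: SimConfig, subject_rng: np.random.Generator, subject_id: str = "S000"
) -> SubjectPair:
    """One subject's before/after session pair.

    The subject's gait style (cadence) is fixed across the two sessions;
    phases and noise are redrawn per session, since the two walks are
    independent.  The after session applies the dose transform with
    ``dose = effect_size · min(brac, 320) / 240``; an abstainer (BrAC 0)
    takes the identical null path as the baseline.
    """
    rng = subject_rng
    cadence = max(0.8, rng.normal(config.cadence_hz, config.cadence_jitter))
    brac_after = _draw_brac(config, rng)
    dose = config.effect_size * min(brac_after, _BRAC_SATURATION) / 240.0

    before = GaitSample(
        subject_id=subject_id,
        session=Session.BEFORE,
        channels=_session_channels(config, rng, cadence, dose=0.0),
        brac=0.0,
    )
    after = GaitSample(
        subject_id=subject_id,
        session=Session.AFTER,
        channels=_session_channels(config, rng, cadence, dose=dose),
        brac=brac_after,
    )
    return SubjectPair(subject_id=subject_id, sample_before=before, sample_after=after)


def simulate_cohort(config: SimConfig) -> list[SubjectPair]:
    """n_subjects independent pairs from per-subject seeded streams.

    Each subject's stream is spawned by index from the root seed, so the
    cohort is bit-identical for a given (config, seed) regardless of
    generation order.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    pairs = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pairs.append(simulate_subject(config, rng, subject_id=f"S{i + 1:03d}"))
    return pairs


def write_cohort(config: SimConfig, out_dir: Path | str) -> list[Path]:
    """Simulate a cohort and write each session to ``out_dir/<subject>/<session>/``."""
    out = Path(out_dir)
    manifests = []
    for pair in simulate_cohort(config):
        for sample in (pair.sample_before, pair.sample_after):
            manifests.append(
                write_session(sample, out / pair.subject_id / sample.session.value)
            )
    return manifests
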