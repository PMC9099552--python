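"""The four per-channel feature families and the 228-feature session vector.

Each of the 12 signal channels (2 devices × 2 sensors × 3 axes) contributes

* 4 spectral features — average one-sided periodogram power in four
  equal-width bands partitioning [0, 31] Hz (31 Hz is the Nyquist frequency
  of the slower device, so bands are comparable across devices),
* 5 statistical features — mean, population standard deviation, population
  variance, minimum, maximum,
* 6 histogram features — fractions of samples in six equal-width bins
  spanning [min, max],
* 4 gait features — zero-crossing rate, mean-crossing rate, median, RMS,

for 19 × 12 = 228 features in a fixed canonical order (sorted by device,
sensor, axis, family, index).  Intoxication-related gait changes — reduced
movement frequency, decreased average acceleration, low-frequency sway —
show up as shifts in these families between a sober baseline session and a
suspect session.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .signal_model import (
    WINDOW_END_S,
    WINDOW_START_S,
    Axis,
    ChannelKey,
    Device,
    GaitSample,
    Sensor,
    all_channel_keys,
    extract_window,
)

__all__ = [
    "FAMILIES",
    "FAMILY_SIZES",
    "N_FEATURES",
    "SPECTRAL_CAP_HZ",
    "N_BANDS",
    "N_HIST_BINS",
    "FeatureVector",
    "canonical_feature_names",
    "parse_feature_name",
    "spectral_band_features",
    "statistical_features",
    "histogram_features",
    "gait_features",
    "extract_features",
]

#: Upper frequency cap shared by both devices: the Nyquist of the 62 Hz band.
SPECTRAL_CAP_HZ = 31.0
N_BANDS = 4
N_HIST_BINS = 6

#: Per-channel feature count by family (canonical family order is
#: alphabetical, matching the canonical name sort).
FAMILY_SIZES = {"gait": 4, "histogram": N_HIST_BINS, "spectral": N_BANDS, "statistical": 5}
FAMILIES = tuple(sorted(FAMILY_SIZES))
N_FEATURES = 12 * sum(FAMILY_SIZES.values())  # 228


def band_masks(n: int, rate: float) -> list[np.ndarray]:
    """Boolean masks assigning the ``n``-sample one-sided spectrum's bins to
    the four equal-width bands of [0, 31] Hz; the last band is right-closed
    so the 31 Hz cap (the slower device's Nyquist) is kept."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    edges = np.linspace(0.0, SPECTRAL_CAP_HZ, N_BANDS + 1)
    masks = []
    for b in range(N_BANDS):
        if b < N_BANDS - 1:
            masks.append((freqs >= edges[b]) & (freqs < edges[b + 1]))
        else:
            masks.append((freqs >= edges[b]) & (freqs <= edges[b + 1]))
    return masks


def spectral_band_features(channel_values: Sequence[float], rate: float) -> np.ndarray:
    """Average one-sided periodogram power in four equal bands over [0, 31] Hz.

    The signal mean is removed before the transform (the DC offset is
    already carried by the statistical family), no taper is applied, and
    the periodogram uses the convention ``P_k = c_k |X_k|^2 / N^2`` with
    ``c_k = 2`` except at DC and (for even N) the Nyquist bin, so that a
    unit-amplitude sinusoid carries total power 1/2.  Each feature is the
    mean of the periodogram bins whose frequency falls in the band; the
    last band is right-closed at 31 Hz.  An all-constant input yields four
    zeros.
    """
    x = np.asarray(channel_values, dtype=np.float64)
    if x.ndim != 1 or len(x) < 8:
        raise ValueError("spectral features need a 1-D signal of length >= 8")
    if not rate > 0:
        raise ValueError("rate must be positive")
    n = len(x)
    spec = np.fft.rfft(x - x.mean())
    power = np.abs(spec) ** 2 / n**2
    scale = np.full(len(power), 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    power *= scale
    out = np.zeros(N_BANDS)
    for b, mask in enumerate(band_masks(n, rate)):
        out[b] = power[mask].mean() if mask.any() else 0.0
    return out


def statistical_features(channel_values: Sequence[float]) -> np.ndarray:
    """Mean, population standard deviation, population variance, min, max."""
    x = np.asarray(channel_values, dtype=np.float64)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("statistical features need a 1-D signal of length >= 2")
    return np.array([x.mean(), x.std(), x.var(), x.min(), x.max()])


def histogram_features(channel_values: Sequence[float]) -> np.ndarray:
    """Fractions of samples in 6 equal-width bins spanning [min, max].

    The last bin is right-closed; fractions sum to 1.  For a constant
    signal (min = max) the whole mass is assigned to the first bin.
    """
    x = np.asarray(channel_values, dtype=np.float64)
    if x.ndim != 1 or len(x) < 1:
        raise ValueError("histogram features need a non-empty 1-D signal")
    lo, hi = x.min(), x.max()
    if lo == hi:
        out = np.zeros(N_HIST_BINS)
        out[0] = 1.0
        return out
    counts, _ = np.histogram(x, bins=N_HIST_BINS, range=(lo, hi))
    return counts / len(x)


def gait_features(channel_values: Sequence[float]) -> np.ndarray:
    """Zero-crossing rate, mean-crossing rate, median, root mean square.

    Crossing rates count consecutive pairs with a strict sign change about
    the reference level (0 for ZCR, the signal mean for MCR), divided by
    n − 1; samples exactly at the reference neither create nor interrupt a
    crossing.
    """
    x = np.asarray(channel_values, dtype=np.float64)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("gait features need a 1-D signal of length >= 2")

    def crossing_rate(y: np.ndarray) -> float:
        return float(np.count_nonzero(y[:-1] * y[1:] < 0)) / (len(y) - 1)

    zcr = crossing_rate(x)
    mcr = crossing_rate(x - x.mean())
    return np.array([zcr, mcr, float(np.median(x)), float(np.sqrt(np.mean(x**2)))])


_FAMILY_FUNCS = {
    "gait": lambda vals, rate: gait_features(vals),
    "histogram": lambda vals, rate: histogram_features(vals),
    "spectral": lambda vals, rate: spectral_band_features(vals, rate),
    "statistical": lambda vals, rate: statistical_features(vals),
}


def canonical_feature_names() -> list[str]:
    """The 228 feature names in canonical order.

    Names are ``device.sensor.axis.family.index`` (index 1-based within the
    family) and the list is sorted by (device, sensor, axis, family, index).
    """
    names = []
    for d, s, a in all_channel_keys():
        for family in FAMILIES:
            for i in range(1, FAMILY_SIZES[family] + 1):
                names.append(f"{d.value}.{s.value}.{a.value}.{family}.{i}")
    return names


def parse_feature_name(name: str) -> tuple[Device, Sensor, Axis, str, int]:
    """Split a canonical feature name into its (device, sensor, axis, family, index)."""
    device, sensor, axis, family, idx = name.split(".")
    return Device(device), Sensor(sensor), Axis(axis), family, int(idx)


@dataclass(frozen=True)
class FeatureVector:
    """An ordered, named 228-feature representation of one session."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "names", tuple(self.names))
        if len(self.names) != N_FEATURES or len(vals) != N_FEATURES:
            raise ValueError(f"feature vector must have exactly {N_FEATURES} entries")
        if list(self.names) != canonical_feature_names():
            raise ValueError("feature names are not in canonical order")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def extract_features(
    sample: GaitSample,
    start_s: float | None = WINDOW_START_S,
    end_s: float | None = WINDOW_END_S,
) -> FeatureVector:
    """Compute the 228-feature vector of a session.

    Each channel is windowed to ``[start_s, end_s)`` seconds (the walk's
    sixth through fourteenth second by default) relative to its own first
    timestamp, then the four family extractors are applied.  Pass
    ``start_s=None`` to skip windowing (e.g. for already-trimmed channels).
    Channel-level failures are re-raised with the channel identity attached.
    """
    names = canonical_feature_names()
    values = np.empty(N_FEATURES)
    pos = 0
    for key in all_channel_keys():
        rec = sample.channels[key]
        try:
            if start_s is not None:
                rec = extract_window(rec, start_s, end_s)
            for family in FAMILIES:
                feats = _FAMILY_FUNCS[family](rec.values, rec.nominal_rate)
                values[pos : pos + FAMILY_SIZES[family]] = feats
                pos += FAMILY_SIZES[family]
        except ValueError as exc:
            d, s, a = key
            raise ValueError(f"channel {d.value}/{s.value}/{a.value}: {exc}") from exc
    return FeatureVector(names=tuple(names), values=values)
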