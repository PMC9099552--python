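"""Domain types and I/O for free-gait motion-sensor sessions.

A session is an 8-second window of free walking recorded simultaneously by
two devices (a smartphone at ~180 Hz and a wrist-worn band at ~62 Hz), each
contributing a tri-axial accelerometer and a tri-axial gyroscope — twelve
signal channels in total — together with a breath-alcohol concentration
(BrAC) reading in micrograms of alcohol per liter of breath.

Channels are stored as raw timestamped series (nanosecond integer
timestamps, as emitted by the devices) and windowed lazily: the analysis
window runs from the sixth to the fourteenth second of the 16 s walk, and
:func:`extract_window` selects it per channel relative to that channel's own
first timestamp.  No cross-device clock alignment or resampling is
performed; every channel is processed independently at its native rate.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Device",
    "Sensor",
    "Axis",
    "Session",
    "ChannelRecording",
    "ChannelKey",
    "GaitSample",
    "SubjectPair",
    "read_session",
    "write_session",
    "extract_window",
    "WINDOW_START_S",
    "WINDOW_END_S",
    "NS_PER_S",
]

NS_PER_S = 1_000_000_000

#: Analysis window boundaries (seconds, half-open) relative to the first
#: timestamp of each channel: the walk's sixth through fourteenth second.
WINDOW_START_S = 6.0
WINDOW_END_S = 14.0


class Device(str, Enum):
    SMARTPHONE = "smartphone"
    WRIST = "wrist"


class Sensor(str, Enum):
    ACCELEROMETER = "accelerometer"
    GYROSCOPE = "gyroscope"


class Axis(str, Enum):
    X = "x"
    Y = "y"
    Z = "z"


class Session(str, Enum):
    BEFORE = "before"
    AFTER = "after"


#: (device, sensor, axis) identity of one signal channel.
ChannelKey = tuple[Device, Sensor, Axis]


def all_channel_keys() -> list[ChannelKey]:
    """The 12 channel identities in canonical (device, sensor, axis) order."""
    return [
        (d, s, a)
        for d in sorted(Device, key=lambda e: e.value)
        for s in sorted(Sensor, key=lambda e: e.value)
        for a in sorted(Axis, key=lambda e: e.value)
    ]


@dataclass(frozen=True)
class ChannelRecording:
    """One axis of one sensor on one device, as a timestamped series.

    Parameters
    ----------
    device, sensor, axis
        Channel identity.
    timestamps
        Strictly increasing integer nanosecond timestamps.
    values
        Sensor readings, same length as ``timestamps`` (accelerometer in
        m/s², gyroscope in rad/s, or device-native units — units are
        metadata and never converted).
    nominal_rate
        Advertised sampling rate in Hz; the median inter-sample interval
        must lie within 20% of ``1 / nominal_rate``.
    """

    device: Device
    sensor: Sensor
    axis: Axis
    timestamps: np.ndarray
    values: np.ndarray
    nominal_rate: float

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=np.int64)
        vals = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vals)
        if ts.ndim != 1 or vals.ndim != 1:
            raise ValueError("timestamps and values must be 1-D")
        if len(ts) != len(vals):
            raise ValueError(
                f"timestamps ({len(ts)}) and values ({len(vals)}) differ in length"
            )
        if len(ts) < 2:
            raise ValueError("a channel needs at least 2 samples")
        if not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not self.nominal_rate > 0:
            raise ValueError("nominal_rate must be positive")
        median_dt = float(np.median(np.diff(ts))) / NS_PER_S
        expected_dt = 1.0 / self.nominal_rate
        if abs(median_dt - expected_dt) > 0.2 * expected_dt:
            raise ValueError(
                f"median sampling interval {median_dt:.6g} s is more than 20% away "
                f"from nominal 1/{self.nominal_rate:g} Hz = {expected_dt:.6g} s"
            )

    @property
    def key(self) -> ChannelKey:
        return (self.device, self.sensor, self.axis)

    @property
    def duration_s(self) -> float:
        """Time spanned from the first to the last sample, in seconds."""
        return float(self.timestamps[-1] - self.timestamps[0]) / NS_PER_S

    @property
    def covered_duration_s(self) -> float:
        """Duration treating each sample as covering one median interval.

        A uniform n-sample recording at rate r covers n/r seconds, so a
        half-open window ``[0, covered_duration_s)`` keeps every sample.
        """
        median_dt = float(np.median(np.diff(self.timestamps)))
        return self.duration_s + median_dt / NS_PER_S


def extract_window(
    rec: ChannelRecording,
    start_s: float = WINDOW_START_S,
    end_s: float = WINDOW_END_S,
) -> ChannelRecording:
    """Select the samples in ``[start_s, end_s)`` seconds after the first timestamp.

    The interval is half-open; timestamps exactly at ``end_s`` are excluded.
    Raises ``ValueError`` if the recording does not cover ``end_s`` seconds
    (coverage counts one sampling interval per sample, so windowing an
    already-windowed recording with the same window length is a no-op).
    """
    if not start_s < end_s:
        raise ValueError("start_s must be strictly less than end_s")
    if rec.covered_duration_s < end_s:
        raise ValueError(
            f"recording covers only {rec.covered_duration_s:.3f} s; "
            f"window requires at least {end_s:g} s"
        )
    t0 = rec.timestamps[0]
    lo = t0 + round(start_s * NS_PER_S)
    hi = t0 + round(end_s * NS_PER_S)
    mask = (rec.timestamps >= lo) & (rec.timestamps < hi)
    return replace(rec, timestamps=rec.timestamps[mask], values=rec.values[mask])


@dataclass(frozen=True)
class GaitSample:
    """One session's 12 signal channels plus the session's BrAC reading."""

    subject_id: str
    session: Session
    channels: Mapping[ChannelKey, ChannelRecording]
    brac: float

    def __post_init__(self) -> None:
        chans = dict(self.channels)
        object.__setattr__(self, "channels", chans)
        if not chans:
            raise ValueError("channel list is empty")
        expected = set(all_channel_keys())
        missing = expected - set(chans)
        extra = set(chans) - expected
        if missing or extra:
            msg = []
            if missing:
                missing_str = ", ".join(
                    f"{d.value}/{s.value}/{a.value}" for d, s, a in sorted(missing)
                )
                msg.append(f"missing channels: {missing_str}")
            if extra:
                msg.append(f"unexpected channels: {sorted(extra)}")
            raise ValueError("; ".join(msg))
        for key, rec in chans.items():
            if rec.key != key:
                raise ValueError(f"channel stored under {key} reports identity {rec.key}")
        if self.brac < 0:
            raise ValueError("brac must be non-negative")

    def channel(self, device: Device, sensor: Sensor, axis: Axis) -> ChannelRecording:
        return self.channels[(device, sensor, axis)]

    def covers_window(
        self, start_s: float = WINDOW_START_S, end_s: float = WINDOW_END_S
    ) -> bool:
        """Whether every channel spans the analysis window."""
        return all(rec.covered_duration_s >= end_s for rec in self.channels.values())


@dataclass(frozen=True)
class SubjectPair:
    """A subject's sober-baseline session and suspect (post-drinking) session."""

    subject_id: str
    sample_before: GaitSample
    sample_after: GaitSample

    def __post_init__(self) -> None:
        if self.sample_before.session is not Session.BEFORE:
            raise ValueError("sample_before must have session='before'")
        if self.sample_after.session is not Session.AFTER:
            raise ValueError("sample_after must have session='after'")
        if not (
            self.subject_id
            == self.sample_before.subject_id
            == self.sample_after.subject_id
        ):
            raise ValueError("subject_id mismatch between pair and samples")


# ---------------------------------------------------------------------------
# Disk format: one CSV per channel (header "timestamp_ns,value") plus a JSON
# manifest naming the subject, session, BrAC reading, and the 12 channel
# files with their device/sensor/axis/nominal-rate tags.
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.json"


def _channel_filename(key: ChannelKey) -> str:
    d, s, a = key
    return f"{d.value}_{s.value}_{a.value}.csv"


def write_session(sample: GaitSample, dir: Path | str) -> Path:
    """Write a session as 12 channel CSVs plus a manifest; return the manifest path."""
    out = Path(dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for key in all_channel_keys():
        rec = sample.channels[key]
        fname = _channel_filename(key)
        with open(out / fname, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["timestamp_ns", "value"])
            for ts, v in zip(rec.timestamps.tolist(), rec.values.tolist()):
                writer.writerow([ts, repr(v)])
        entries.append(
            {
                "device": rec.device.value,
                "sensor": rec.sensor.value,
                "axis": rec.axis.value,
                "nominal_rate": rec.nominal_rate,
                "file": fname,
            }
        )
    manifest = {
        "subject_id": sample.subject_id,
        "session": sample.session.value,
        "brac": sample.brac,
        "channels": entries,
    }
    manifest_path = out / MANIFEST_NAME
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest_path


def _read_channel_csv(path: Path) -> tuple[np.ndarray, np.ndarray]:
    ts: list[int] = []
    vals: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["timestamp_ns", "value"]:
            raise ValueError(f"{path}: expected header 'timestamp_ns,value'")
        for row in reader:
            if not row:
                continue
            ts.append(int(row[0]))
            vals.append(float(row[1]))
    return np.asarray(ts, dtype=np.int64), np.asarray(vals, dtype=np.float64)


def read_session(manifest_path: Path | str) -> GaitSample:
    """Load a session from its manifest, validating channel completeness.

    Raises ``ValueError`` listing absent (device, sensor, axis) combinations
    if channels are missing, or naming the offending file on non-monotone
    timestamps.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    channels: dict[ChannelKey, ChannelRecording] = {}
    for entry in manifest.get("channels", []):
        key: ChannelKey = (
            Device(entry["device"]),
            Sensor(entry["sensor"]),
            Axis(entry["axis"]),
        )
        path = base / entry["file"]
        ts, vals = _read_channel_csv(path)
        if len(ts) >= 2 and not np.all(np.diff(ts) > 0):
            raise ValueError(f"{path}: timestamps are not strictly increasing")
        channels[key] = ChannelRecording(
            device=key[0],
            sensor=key[1],
            axis=key[2],
            timestamps=ts,
            values=vals,
            nominal_rate=float(entry["nominal_rate"]),
        )
    missing = set(all_channel_keys()) - set(channels)
    if missing:
        missing_str = ", ".join(
            f"{d.value}/{s.value}/{a.value}" for d, s, a in sorted(missing)
        )
        raise ValueError(f"{manifest_path}: missing channels: {missing_str}")
    return GaitSample(
        subject_id=str(manifest["subject_id"]),
        session=Session(manifest["session"]),
        channels=channels,
        brac=float(manifest["brac"]),
    )
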