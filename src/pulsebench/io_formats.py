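"""Stream containers and CSV readers/writers.

All internal times are seconds since the start of the recording (float).
On disk, R-R streams carry ISO-8601 UTC timestamps; waveforms and beat
series carry relative time in seconds. Devices in a study are assumed to
be synchronised to UTC, so a shared absolute ``start_time`` is enough to
place every stream on one timeline.
"""

from __future__ import annotations

import dataclasses
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Waveform",
    "RRStream",
    "LabelTrack",
    "SchemaError",
    "FormatError",
    "read_rr_stream",
    "write_rr_stream",
    "read_waveform",
    "write_waveform",
    "read_beats",
    "write_beats",
    "read_label_track",
    "write_label_track",
]

POSTURE_VOCAB = frozenset(
    {"upright", "reclined", "lying right", "lying left", "prone", "supine"}
)
ACTIVITY_VOCAB = frozenset({"cycling", "rest", "walking", "running"})
LABEL_KINDS = ("posture", "activity", "sleep_state", "hand")

_EPOCH0 = datetime(2022, 11, 1, 0, 0, 0, tzinfo=timezone.utc)


class SchemaError(ValueError):
    """A file does not match the expected column schema."""


class FormatError(ValueError):
    """A file matches the schema but violates a format contract."""


@dataclasses.dataclass
class Waveform:
    """Uniformly sampled signal (PPG or ECG)."""

    samples: np.ndarray
    fs_hz: float
    start_time: datetime = _EPOCH0
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n / self.fs_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n) / self.fs_hz


@dataclasses.dataclass
class RRStream:
    """Raw timestamped beat-to-beat intervals as a device emitted them.

    Record order is preserved exactly as read: the stream is *not*
    guaranteed sorted or duplicate-free — cleaning owns that.
    ``time_s`` is seconds relative to ``start_time``.
    """

    time_s: np.ndarray
    rr_ms: np.ndarray
    device: str = ""
    start_time: datetime = _EPOCH0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if self.time_s.shape != self.rr_ms.shape:
            raise ValueError("time_s and rr_ms must have equal length")
        finite = self.rr_ms[np.isfinite(self.rr_ms)]
        if finite.size and np.any(finite <= 0):
            raise ValueError("rr_ms must be positive where present")

    def __len__(self) -> int:
        return int(self.time_s.size)


@dataclasses.dataclass
class LabelTrack:
    """Interval annotations (posture / activity / sleep state / hand)."""

    start_s: np.ndarray
    end_s: np.ndarray
    kind: np.ndarray  # element of LABEL_KINDS per row
    value: np.ndarray

    def __post_init__(self) -> None:
        self.start_s = np.asarray(self.start_s, dtype=float)
        self.end_s = np.asarray(self.end_s, dtype=float)
        self.kind = np.asarray(self.kind, dtype=object)
        self.value = np.asarray(self.value, dtype=object)
        if np.any(self.end_s <= self.start_s):
            raise ValueError("label intervals require start < end")
        for k, v in zip(self.kind, self.value):
            if k == "posture" and v not in POSTURE_VOCAB:
                raise ValueError(f"unknown posture label {v!r}")
            if k == "activity" and v not in ACTIVITY_VOCAB:
                raise ValueError(f"unknown activity label {v!r}")

    def __len__(self) -> int:
        return int(self.start_s.size)

    def select(self, kind: str) -> "LabelTrack":
        m = self.kind == kind
        return LabelTrack(self.start_s[m], self.end_s[m], self.kind[m], self.value[m])


# ---------------------------------------------------------------------------
# R-R streams


def _parse_iso(s: str) -> datetime:
    dt = datetime.fromisoformat(str(s))
    if dt.tzinfo is None:
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.astimezone(timezone.utc)


def read_rr_stream(path: str | Path, device_label: str = "") -> RRStream:
    """Read a ``timestamp_iso,rr_ms`` CSV, preserving file order.

    Malformed rows raise :class:`FormatError` with the 1-based data line
    number so a dirty export can be located and fixed.
    """
    df = pd.read_csv(path, dtype=str)
    missing = {"timestamp_iso", "rr_ms"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        return RRStream(np.empty(0), np.empty(0), device=device_label)
    times: list[datetime] = []
    rrs: list[float] = []
    for line_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            times.append(_parse_iso(row.timestamp_iso))
        except (ValueError, TypeError) as exc:
            raise FormatError(
                f"{path}: line {line_no}: bad timestamp {row.timestamp_iso!r}"
            ) from exc
        try:
            rrs.append(float(row.rr_ms))
        except (ValueError, TypeError) as exc:
            raise FormatError(
                f"{path}: line {line_no}: bad rr_ms {row.rr_ms!r}"
            ) from exc
    start = min(times)
    rel = np.array([(t - start).total_seconds() for t in times])
    return RRStream(rel, np.array(rrs), device=device_label, start_time=start)


def write_rr_stream(stream: RRStream, path: str | Path) -> None:
    stamps = [
        (stream.start_time + timedelta(seconds=float(t))).isoformat()
        for t in stream.time_s
    ]
    pd.DataFrame({"timestamp_iso": stamps, "rr_ms": stream.rr_ms}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Waveforms


def read_waveform(
    path: str | Path, fs_hz: float | None = None, channel_label: str = ""
) -> Waveform:
    """Read a ``time_s,value`` CSV with uniform sample spacing.

    Spacing must be uniform within 1% of the nominal sample period; a
    dropped sample is a :class:`FormatError`, not something to silently
    interpolate over.
    """
    df = pd.read_csv(path)
    missing = {"time_s", "value"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    v = df["value"].to_numpy(dtype=float)
    if t.size >= 2:
        dt = np.diff(t)
        period = 1.0 / fs_hz if fs_hz else float(np.median(dt))
        if np.any(np.abs(dt - period) > 0.01 * period):
            bad = int(np.argmax(np.abs(dt - period) > 0.01 * period))
            raise FormatError(
                f"{path}: non-uniform sample spacing near row {bad + 1} "
                f"(expected {period:.6g} s, got {dt[bad]:.6g} s)"
            )
        fs = 1.0 / period
    else:
        if fs_hz is None:
            raise FormatError(f"{path}: cannot infer fs from < 2 samples")
        fs = fs_hz
    return Waveform(v, fs_hz=fs, channel_label=channel_label)


def write_waveform(w: Waveform, path: str | Path) -> None:
    pd.DataFrame({"time_s": w.time_s, "value": w.samples}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Beat series (times only; full BeatSeries lives in pulsebench.ppgbeats)


def read_beats(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise SchemaError(f"{path}: missing column 'time_s'")
    return df["time_s"].to_numpy(dtype=float)


def write_beats(times_s: Sequence[float], path: str | Path, detector: str = "") -> None:
    df = pd.DataFrame({"time_s": np.asarray(times_s, dtype=float)})
    if detector:
        df["detector"] = detector
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Label tracks


def read_label_track(path: str | Path) -> LabelTrack:
    df = pd.read_csv(path)
    missing = {"start_s", "end_s", "kind", "value"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return LabelTrack(
        df["start_s"].to_numpy(float),
        df["end_s"].to_numpy(float),
        df["kind"].to_numpy(object),
        df["value"].to_numpy(object),
    )


def write_label_track(track: LabelTrack, path: str | Path) -> None:
    pd.DataFrame(
        {
            "start_s": track.start_s,
            "end_s": track.end_s,
            "kind": track.kind,
            "value": track.value,
        }
    ).to_csv(path, index=False)
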