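"""Reading, writing and basic conditioning of 6-axis inertial sensor streams.

The expected on-disk format is the CSV export of a wearable logger:
``timestamp,ax,ay,az[,gx,gy,gz][,label]`` with accelerometer channels in g
and gyroscope channels in degrees per second (dps), nominally sampled at
100 Hz.  The timestamp column is carried for human readability only; the
sample index together with the declared sampling rate is authoritative.

Ground-truth activity labels may arrive inline (one label column per
sample) or as a separate interval annotation file
(``start_s,end_s,label``); both normalise to per-sample labels on the
:class:`IMURecording`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ACCEL_RANGE_G",
    "GYRO_RANGE_DPS",
    "CLASSES",
    "STROKE_CLASSES",
    "CHANNEL_NAMES",
    "IMURecording",
    "AnnotationTrack",
    "ParseError",
    "ColumnCountError",
    "NonNumericValueError",
    "UnknownLabelError",
    "read_recording_csv",
    "write_recording_csv",
    "read_annotations_csv",
    "write_annotations_csv",
    "apply_annotations",
    "clip_to_range",
    "subsample",
]

#: Full-scale sensor ranges; values outside are physically impossible for the
#: logger and are truncated on ingest.
ACCEL_RANGE_G = 16.0
GYRO_RANGE_DPS = 2000.0

#: The nine-class activity vocabulary: seven badminton strokes plus the two
#: non-stroke activities (running between strokes, standing still).
STROKE_CLASSES = (
    "clear",
    "dab",
    "drive",
    "short_serve",
    "lob",
    "netdrop",
    "smash",
)
CLASSES = STROKE_CLASSES + ("displacement", "rest")

CHANNEL_NAMES = ("ax", "ay", "az", "gx", "gy", "gz")


class ParseError(ValueError):
    """Base class for sensor/annotation CSV parse failures."""


class ColumnCountError(ParseError):
    """A data row has the wrong number of columns."""


class NonNumericValueError(ParseError):
    """A channel field could not be parsed as a finite number."""


class UnknownLabelError(ParseError):
    """A label string is not in the nine-class vocabulary."""


def _check_labels(labels: Sequence[str]) -> None:
    unknown = set(labels) - set(CLASSES)
    if unknown:
        raise UnknownLabelError(
            f"unknown activity label(s) {sorted(unknown)}; expected one of {list(CLASSES)}"
        )


@dataclass
class IMURecording:
    """A timestamped multi-channel inertial stream with optional per-sample labels.

    Parameters
    ----------
    fs_hz : float
        Sampling frequency in Hz; must be positive.
    samples : ndarray of shape (N, C)
        Channel order ``(ax, ay, az)`` for C=3 or ``(ax, ay, az, gx, gy, gz)``
        for C=6; accelerometer in g, gyroscope in dps.
    labels : ndarray of str or None
        Per-sample activity labels over the nine-class vocabulary.
    subject_id : str, optional
        Identifier of the player who produced the stream.
    """

    fs_hz: float
    samples: np.ndarray
    labels: np.ndarray | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs_hz}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] not in (3, 6):
            raise ValueError(
                f"samples must be an (N, 3) or (N, 6) array, got shape {self.samples.shape}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != len(self.samples):
                raise ValueError(
                    f"labels length {len(self.labels)} != sample count {len(self.samples)}"
                )
            _check_labels(self.labels)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class AnnotationTrack:
    """Interval ground-truth annotations: ``(start_s, end_s, label)`` triples."""

    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for start, end, label in self.intervals:
            if not start < end:
                raise ValueError(f"interval start {start} must precede end {end}")
        _check_labels([lab for _, _, lab in self.intervals])

    def validate_nonoverlapping(self) -> None:
        ordered = sorted(self.intervals, key=lambda iv: iv[0])
        for (s0, e0, l0), (s1, e1, l1) in zip(ordered, ordered[1:]):
            if s1 < e0:
                raise ValueError(
                    f"overlapping annotation intervals ({s0}, {e0}, {l0}) and ({s1}, {e1}, {l1})"
                )


def _looks_like_header(row: list[str], n_channels: int) -> bool:
    # A header row has non-numeric text in the channel positions.
    for value in row[1 : 1 + n_channels]:
        try:
            float(value)
        except ValueError:
            return True
    return False


def read_recording_csv(
    path: str | Path, fs_hz: float, has_labels: bool = False
) -> IMURecording:
    """Read a sensor CSV stream (``timestamp,ax,ay,az[,gx,gy,gz][,label]``).

    The channel count (3 or 6) is inferred from the first data row.  An
    optional header row is skipped.  Malformed rows raise a
    :class:`ParseError` subclass naming the offending 1-based row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sensor CSV not found: {path}")

    rows: list[list[float]] = []
    labels: list[str] = []
    n_channels: int | None = None
    with open(path, newline="") as fh:
        for row_no, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not f.strip() for f in row):
                continue
            if n_channels is None:
                width = len(row) - 1 - (1 if has_labels else 0)
                if width not in (3, 6):
                    if _looks_like_header(row, max(width, 3)):
                        continue
                    raise ColumnCountError(
                        f"row {row_no}: expected timestamp + 3 or 6 channels"
                        f"{' + label' if has_labels else ''}, got {len(row)} columns"
                    )
                if _looks_like_header(row, width):
                    n_channels = width
                    continue
                n_channels = width
            expected = 1 + n_channels + (1 if has_labels else 0)
            if len(row) != expected:
                raise ColumnCountError(
                    f"row {row_no}: expected {expected} columns, got {len(row)}"
                )
            values = []
            for col, fieldval in zip(CHANNEL_NAMES, row[1 : 1 + n_channels]):
                try:
                    x = float(fieldval)
                except ValueError:
                    x = float("nan")
                if not np.isfinite(x):
                    raise NonNumericValueError(
                        f"row {row_no}: channel {col} value {fieldval!r} is not a finite number"
                    )
                values.append(x)
            rows.append(values)
            if has_labels:
                labels.append(row[-1].strip())

    if not rows:
        raise ParseError(f"{path}: no data rows")
    samples = np.asarray(rows, dtype=float)
    return IMURecording(
        fs_hz=fs_hz,
        samples=samples,
        labels=np.asarray(labels, dtype=object) if has_labels else None,
    )


def write_recording_csv(
    path: str | Path, rec: IMURecording, decimals: int = 6
) -> None:
    """Write a recording back to sensor CSV, with header and timestamps."""
    header = ["timestamp"] + list(CHANNEL_NAMES[: rec.n_channels])
    if rec.labels is not None:
        header.append("label")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for i in range(rec.n_samples):
            row = [f"{i / rec.fs_hz:.6f}"] + [
                f"{v:.{decimals}f}" for v in rec.samples[i]
            ]
            if rec.labels is not None:
                row.append(str(rec.labels[i]))
            writer.writerow(row)


def read_annotations_csv(path: str | Path) -> AnnotationTrack:
    """Read an interval annotation CSV (``start_s,end_s,label``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation CSV not found: {path}")
    intervals: list[tuple[float, float, str]] = []
    with open(path, newline="") as fh:
        for row_no, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not f.strip() for f in row):
                continue
            if len(row) < 3:
                raise ColumnCountError(
                    f"row {row_no}: expected start_s,end_s,label, got {len(row)} columns"
                )
            try:
                start, end = float(row[0]), float(row[1])
            except ValueError:
                if row_no == 1:  # header
                    continue
                raise NonNumericValueError(
                    f"row {row_no}: non-numeric interval bounds {row[:2]}"
                ) from None
            intervals.append((start, end, row[2].strip()))
    return AnnotationTrack(intervals)


def write_annotations_csv(path: str | Path, track: AnnotationTrack) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["start_s", "end_s", "label"])
        for start, end, label in track.intervals:
            writer.writerow([f"{start:.6f}", f"{end:.6f}", label])


def apply_annotations(
    rec: IMURecording, track: AnnotationTrack, default: str = "rest"
) -> IMURecording:
    """Paint interval annotations onto per-sample labels.

    A sample at index ``i`` belongs to an interval when its time ``i / fs``
    falls in ``[start_s, end_s)``.  Samples outside every interval receive
    the ``default`` class.  Overlapping intervals are rejected.
    """
    _check_labels([default])
    track.validate_nonoverlapping()
    labels = np.full(rec.n_samples, default, dtype=object)
    for start, end, label in track.intervals:
        if end > rec.duration_s + 0.5 / rec.fs_hz:
            raise ValueError(
                f"annotation interval ({start}, {end}) exceeds recording "
                f"duration {rec.duration_s:.3f} s"
            )
        lo = int(np.ceil(start * rec.fs_hz - 1e-9))
        hi = int(np.ceil(end * rec.fs_hz - 1e-9))
        labels[lo : min(hi, rec.n_samples)] = label
    return replace(rec, labels=labels)


def clip_to_range(rec: IMURecording) -> IMURecording:
    """Truncate accelerometer to ±16 g and gyroscope to ±2000 dps."""
    clipped = rec.samples.copy()
    clipped[:, :3] = np.clip(clipped[:, :3], -ACCEL_RANGE_G, ACCEL_RANGE_G)
    if rec.n_channels == 6:
        clipped[:, 3:] = np.clip(clipped[:, 3:], -GYRO_RANGE_DPS, GYRO_RANGE_DPS)
    return replace(rec, samples=clipped)


def subsample(rec: IMURecording, target_hz: float) -> IMURecording:
    """Decimate to ``target_hz`` by keeping every k-th sample starting at 0.

    The decimation factor ``k = fs_hz / target_hz`` must be a positive
    integer (100 → 12.5 Hz gives k = 8).  No anti-alias filter is applied:
    the classifiers learn raw signal patterns and magnitudes, which
    filtering would distort.  Labels are decimated identically.
    """
    ratio = rec.fs_hz / target_hz
    k = round(ratio)
    if k < 1 or abs(ratio - k) > 1e-9:
        raise ValueError(
            f"cannot subsample {rec.fs_hz} Hz to {target_hz} Hz: "
            f"decimation factor {ratio} is not a positive integer"
        )
    return replace(
        rec,
        fs_hz=target_hz,
        samples=rec.samples[::k].copy(),
        labels=None if rec.labels is None else rec.labels[::k].copy(),
    )
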