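"""Signal scaling, non-overlapping frame segmentation and channel selection.

Classifier inputs are raw scaled frames: the stream is divided into
fixed-duration, non-overlapping windows, each labelled with the modal
per-sample ground-truth class.  Scaling divides every sample of a modality
by one global constant (the sensor full-scale range by default) rather
than normalising per frame — absolute magnitudes carry class information
and must stay comparable across frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .signal_io import CHANNEL_NAMES, CLASSES, IMURecording

__all__ = [
    "ScaleSpec",
    "Frame",
    "FrameSet",
    "scale",
    "segment_frames",
    "majority_label",
    "select_channels",
    "detect_impact_peak",
    "save_frameset",
    "load_frameset",
]

FRAMESET_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ScaleSpec:
    """Per-modality scaling divisors (defaults = sensor full-scale ranges)."""

    accel_scale: float = 16.0
    gyro_scale: float = 2000.0

    def __post_init__(self) -> None:
        if self.accel_scale <= 0 or self.gyro_scale <= 0:
            raise ValueError(
                f"scale divisors must be positive, got {self.accel_scale}, {self.gyro_scale}"
            )


@dataclass
class Frame:
    """One fixed-length window: an L×C matrix, its majority label, and the
    sample offset at which it starts in the source recording."""

    data: np.ndarray
    label: str
    start_index: int


@dataclass
class FrameSet:
    """Ordered, disjoint, consecutive fixed-length frames at one frame size."""

    frame_size_s: float
    fs_hz: float
    frames: list[Frame]
    class_vocab: tuple[str, ...] = CLASSES

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_len(self) -> int:
        return round(self.frame_size_s * self.fs_hz)

    @property
    def n_channels(self) -> int:
        return self.frames[0].data.shape[1] if self.frames else 0

    @property
    def X(self) -> np.ndarray:
        """Stacked frame windows, shape (n_frames, L, C)."""
        if not self.frames:
            return np.empty((0, self.frame_len, 0))
        return np.stack([f.data for f in self.frames])

    @property
    def y(self) -> np.ndarray:
        """Frame labels, shape (n_frames,)."""
        return np.asarray([f.label for f in self.frames], dtype=object)


def scale(rec: IMURecording, spec: ScaleSpec = ScaleSpec()) -> IMURecording:
    """Divide accelerometer channels by ``accel_scale`` and gyroscope channels
    by ``gyro_scale``.  No per-frame statistics are involved, so relative
    magnitudes between any two frames are preserved exactly."""
    scaled = rec.samples.copy()
    scaled[:, :3] /= spec.accel_scale
    if rec.n_channels == 6:
        scaled[:, 3:] /= spec.gyro_scale
    return replace(rec, samples=scaled)


def majority_label(window_labels: Sequence[str]) -> str:
    """Modal label of a window; ties broken by earliest first occurrence."""
    if len(window_labels) == 0:
        raise ValueError("cannot take the majority label of an empty window")
    counts: dict[str, int] = {}
    for lab in window_labels:  # insertion order = first-occurrence order
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    for lab, n in counts.items():
        if n == best:
            return lab
    raise AssertionError("unreachable")


def segment_frames(
    rec: IMURecording,
    frame_size_s: float,
    class_vocab: tuple[str, ...] = CLASSES,
) -> FrameSet:
    """Cut a labelled recording into non-overlapping fixed-duration frames.

    Frame length is ``L = round(frame_size_s * fs_hz)`` samples; the stream
    yields ``floor(N / L)`` frames and the trailing partial window is
    dropped.  Each frame takes the majority vote of its per-sample labels.
    A frame longer than the recording yields an empty FrameSet.
    """
    if rec.labels is None:
        raise ValueError("recording must be labelled before segmentation")
    L = round(frame_size_s * rec.fs_hz)
    if L < 1:
        raise ValueError(
            f"frame size {frame_size_s} s at {rec.fs_hz} Hz gives zero-length frames"
        )
    n_frames = rec.n_samples // L
    frames = [
        Frame(
            data=rec.samples[i * L : (i + 1) * L].copy(),
            label=majority_label(rec.labels[i * L : (i + 1) * L]),
            start_index=i * L,
        )
        for i in range(n_frames)
    ]
    return FrameSet(
        frame_size_s=frame_size_s,
        fs_hz=rec.fs_hz,
        frames=frames,
        class_vocab=class_vocab,
    )


def select_channels(
    fs: FrameSet, mode: Literal["accel_only", "accel_gyro"]
) -> FrameSet:
    """Keep the accelerometer triplet only, or all six channels."""
    if mode not in ("accel_only", "accel_gyro"):
        raise ValueError(f"unknown channel mode {mode!r}")
    if mode == "accel_gyro":
        if fs.frames and fs.n_channels != 6:
            raise ValueError(
                f"accel_gyro requires 6 channels, frame set has {fs.n_channels}"
            )
        return fs
    frames = [
        Frame(data=f.data[:, :3].copy(), label=f.label, start_index=f.start_index)
        for f in fs.frames
    ]
    return replace(fs, frames=frames)


def detect_impact_peak(
    frame: Frame, channel: str = "ay", threshold: float = 0.5
) -> int | None:
    """Locate a shuttle-impact spike as a jump in the first difference.

    Hitting the shuttle leaves a very short, high-magnitude excursion
    (typically on the accelerometer y axis when the sensor sits on the
    racket grip), which stands out in the signal's derivative.  Returns the
    index of the first sample whose absolute first difference from its
    predecessor exceeds ``threshold`` (signal units per sample), or None.
    """
    if channel not in CHANNEL_NAMES:
        raise ValueError(f"unknown channel {channel!r}")
    idx = CHANNEL_NAMES.index(channel)
    if idx >= frame.data.shape[1]:
        raise ValueError(
            f"channel {channel!r} not present in a {frame.data.shape[1]}-channel frame"
        )
    if frame.data.shape[0] < 2:
        raise ValueError("impact detection needs at least two samples")
    diffs = np.abs(np.diff(frame.data[:, idx]))
    hits = np.nonzero(diffs > threshold)[0]
    return int(hits[0]) + 1 if hits.size else None


def save_frameset(path: str | Path, fs: FrameSet) -> None:
    """Persist a FrameSet as an .npz matrix container plus a JSON sidecar."""
    path = Path(path)
    np.savez(Path(str(path) + ".npz"),
        X=fs.X.astype(float),
        start_index=np.asarray([f.start_index for f in fs.frames], dtype=int),
    )
    sidecar = Path(str(path) + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "format_version": FRAMESET_FORMAT_VERSION,
                "frame_size_s": fs.frame_size_s,
                "fs_hz": fs.fs_hz,
                "class_vocab": list(fs.class_vocab),
                "labels": [f.label for f in fs.frames],
            }
        )
    )


def load_frameset(path: str | Path) -> FrameSet:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    if meta["format_version"] != FRAMESET_FORMAT_VERSION:
        raise ValueError(f"unsupported FrameSet format version {meta['format_version']}")
    with np.load(Path(str(path) + ".npz")) as arrays:
        X = arrays["X"]
        starts = arrays["start_index"]
    frames = [
        Frame(data=X[i], label=meta["labels"][i], start_index=int(starts[i]))
        for i in range(len(meta["labels"]))
    ]
    return FrameSet(
        frame_size_s=meta["frame_size_s"],
        fs_hz=meta["fs_hz"],
        frames=frames,
        class_vocab=tuple(meta["class_vocab"]),
    )
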