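"""End-to-end synthetic experiment drivers.

These functions reproduce the pipeline's headline behaviours on generated
two-subject data at desk scale: the frame-count bookkeeping of a full
session, the multi-frame-size ensemble against its best single member,
the contribution of the gyroscope on the accelerometer-similar
drive/clear pair, and cross-subject recovery of a single CNN.  They are
used by both the test suite and the reproduction script.

Problem sizes are deliberately modest — a few hundred strokes per run,
25 Hz for the multi-model studies (the rate the sampling-frequency study
recommends as sufficient) and reduced epochs — so a full pass runs in
minutes on one CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import FrameSizeEnsemble, align_predictions, fuse
from .evaluation import event_accuracy
from .models import CNNClassifier
from .preprocessing import scale, segment_frames, select_channels
from .signal_io import CLASSES, IMURecording, STROKE_CLASSES, subsample
from .synthetic import ScenarioConfig, generate_two_subject_split

__all__ = [
    "frame_count_identity",
    "ensemble_superiority",
    "channel_ablation",
    "cross_subject_recovery",
    "EnsembleRun",
]

#: Scaled-down per-class stroke count used by the training-heavy studies.
STUDY_COUNTS = {c: 10 for c in STROKE_CLASSES}
STUDY_DRILL_REPEATS = 10
STUDY_EPOCHS = 30


def frame_count_identity(n_samples: int = 663_954, fs_hz: float = 100.0,
                         frame_size_s: float = 1.0) -> int:
    """Number of 1 s frames a full-session stream yields at 100 Hz."""
    labels = np.full(n_samples, "rest", dtype=object)
    rec = IMURecording(fs_hz=fs_hz, samples=np.zeros((n_samples, 6)), labels=labels)
    return len(segment_frames(rec, frame_size_s))


def _two_subject(seed: int, target_hz: float) -> tuple[IMURecording, IMURecording]:
    cfg = ScenarioConfig(counts=dict(STUDY_COUNTS), seed=seed)
    train, test = generate_two_subject_split(
        cfg, subject_jitter=0.1, drill_repeats=STUDY_DRILL_REPEATS)
    if target_hz != cfg.fs_hz:
        train, test = subsample(train, target_hz), subsample(test, target_hz)
    return train, test


@dataclass
class EnsembleRun:
    """One seed of the frame-size-ensemble study (event-level accuracies)."""

    seed: int
    single_accuracies: list[float]
    fused_accuracy: float

    @property
    def best_single(self) -> float:
        return max(self.single_accuracies)


def ensemble_superiority(seed: int, n_seeds: int = 5,
                         target_hz: float = 25.0) -> list[EnsembleRun]:
    """Duration-weighted ensemble vs its best single-frame-size member.

    Per seed, a seven-model bank is trained on synthetic subject A and
    fused (duration-matched weights, softmax averaging) on subject B's
    scenario; stroke-sequence (per-event) accuracy is compared with each
    single model's.
    """
    runs: list[EnsembleRun] = []
    for i in range(1, n_seeds + 1):
        s = seed + i
        train_rec, test_rec = _two_subject(s, target_hz)
        ens = FrameSizeEnsemble(epochs=STUDY_EPOCHS, weights="duration",
                                random_state=s).fit(train_rec)
        truth = test_rec.labels
        singles = []
        for model in ens.models_:
            idx, _ = fuse(align_predictions([model], test_rec))
            singles.append(event_accuracy(truth, model.classes_[idx]))
        fused = ens.predict(test_rec)
        runs.append(EnsembleRun(
            seed=s,
            single_accuracies=singles,
            fused_accuracy=event_accuracy(truth, fused),
        ))
    return runs


def channel_ablation(seed: int, n_seeds: int = 3, frame_size_s: float = 1.2,
                     target_hz: float = 25.0) -> dict[str, float]:
    """Drive/clear pair accuracy without vs with the gyroscope.

    The pair shares its linear-acceleration structure, so dropping the
    angular-rate channels should cost accuracy on exactly these strokes.
    Returns mean pair (drive, clear) event accuracies per channel mode.
    """
    sums = {"accel_only": 0.0, "accel_gyro": 0.0}
    for i in range(1, n_seeds + 1):
        s = seed + i
        train_rec, test_rec = _two_subject(s, target_hz)
        for mode in sums:
            fs_tr = select_channels(segment_frames(scale(train_rec), frame_size_s), mode)
            model = CNNClassifier(epochs=STUDY_EPOCHS, val_fraction=0.0,
                                  random_state=s, classes=fs_tr.class_vocab,
                                  ).fit(fs_tr.X, fs_tr.y)
            idx, _ = fuse(align_predictions([model], test_rec, channel_mode=mode))
            sums[mode] += event_accuracy(test_rec.labels, model.classes_[idx],
                                         classes=("drive", "clear"))
    return {mode: total / n_seeds for mode, total in sums.items()}


def cross_subject_recovery(seed: int, frame_size_s: float = 0.8,
                           fs_hz: float = 100.0) -> float:
    """Frame-level accuracy of a CNN trained on subject A, tested on B.

    Subjects differ by 10% multiplicative amplitude and duration jitter;
    the per-frame accuracy on subject B's scenario measures how much of
    the class structure survives the subject change.
    """
    train_rec, test_rec = _two_subject(seed + 1, fs_hz)
    fs_tr = segment_frames(scale(train_rec), frame_size_s)
    fs_te = segment_frames(scale(test_rec), frame_size_s)
    model = CNNClassifier(epochs=STUDY_EPOCHS, val_fraction=0.0,
                          random_state=seed, classes=fs_tr.class_vocab,
                          ).fit(fs_tr.X, fs_tr.y)
    return float(np.mean(model.predict(fs_te.X) == fs_te.y))
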