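import numpy as np
import pytest

from shuttlesense.preprocessing import scale, segment_frames
from shuttlesense.signal_io import CLASSES, IMURecording, subsample
from shuttlesense.synthetic import ScenarioConfig, generate_scenario, generate_two_subject_split

STROKES = ("clear", "dab", "drive", "short_serve", "lob", "netdrop", "smash")


@pytest.fixture(scope="session")
def small_counts():
    return {c: 4 for c in STROKES}


@pytest.fixture(scope="session")
def small_scenario(small_counts):
    """A short labelled varied-play recording at 100 Hz."""
    return generate_scenario(ScenarioConfig(counts=small_counts, displacement_bouts=2, seed=7))


@pytest.fixture(scope="session")
def two_subject_25hz(small_counts):
    """A train/test subject pair subsampled to 25 Hz (cheap to train on)."""
    cfg = ScenarioConfig(counts=small_counts, displacement_bouts=2, seed=11)
    train, test = generate_two_subject_split(cfg, subject_jitter=0.1, drill_repeats=4)
    return subsample(train, 25), subsample(test, 25)


@pytest.fixture(scope="session")
def separable_frames():
    """A linearly separable two-class frame problem: constant-sign windows."""
    rng = np.random.default_rng(42)
    L, C, n = 20, 6, 60
    X = np.empty((n, L, C))
    y = np.empty(n, dtype=object)
    for i in range(n):
        sign = 1.0 if i % 2 == 0 else -1.0
        X[i] = sign * 0.5 + rng.normal(0, 0.05, size=(L, C))
        y[i] = "smash" if sign > 0 else "rest"
    return X, y


@pytest.fixture
def labelled_recording():
    """Tiny deterministic labelled recording for framing tests."""
    rng = np.random.default_rng(0)
    n = 250
    labels = np.array(["rest"] * 100 + ["smash"] * 80 + ["clear"] * 70, dtype=object)
    return IMURecording(fs_hz=100.0, samples=rng.normal(size=(n, 6)), labels=labels)
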