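import numpy as np
import pytest

from shuttlesense.signal_io import CLASSES, STROKE_CLASSES, clip_to_range
from shuttlesense.synthetic import (
    DEFAULT_TEMPLATES,
    DEFAULT_TEST_COUNTS,
    ScenarioConfig,
    generate_scenario,
    generate_stroke,
    generate_two_subject_split,
    mirror_left_handed,
)


class TestGenerateStroke:
    def test_deterministic_under_seed(self):
        t = DEFAULT_TEMPLATES["smash"]
        a = generate_stroke(t, np.random.default_rng(9), noise_sd=0.05)
        b = generate_stroke(t, np.random.default_rng(9), noise_sd=0.05)
        np.testing.assert_array_equal(a, b)

    def test_length_tracks_duration(self):
        for name, t in DEFAULT_TEMPLATES.items():
            burst = generate_stroke(t, np.random.default_rng(0), fs_hz=100.0)
            assert burst.shape[1] == 6
            assert abs(len(burst) / 100.0 - t.duration_s) <= 4 * t.duration_sd_s + 0.02

    def test_within_clip_range(self):
        from shuttlesense.signal_io import IMURecording

        for t in DEFAULT_TEMPLATES.values():
            burst = generate_stroke(t, np.random.default_rng(1), noise_sd=0.05, spike=True)
            rec = IMURecording(fs_hz=100, samples=burst)
            np.testing.assert_allclose(clip_to_range(rec).samples, burst, atol=1e-9)

    def test_spike_is_local(self):
        t = DEFAULT_TEMPLATES["smash"]
        with_spike = generate_stroke(t, np.random.default_rng(2), spike=True)
        without = generate_stroke(t, np.random.default_rng(2), spike=False)
        diff = np.nonzero((with_spike != without).any(axis=1))[0]
        assert 1 <= len(diff) <= 3
        assert (with_spike[:, [0, 2, 3, 4, 5]] == without[:, [0, 2, 3, 4, 5]]).all()

    def test_spike_dominates_first_difference(self):
        """Guarantees a first-difference detector can find the impact."""
        t = DEFAULT_TEMPLATES["smash"]
        with_spike = generate_stroke(t, np.random.default_rng(3), spike=True)
        without = generate_stroke(t, np.random.default_rng(3), spike=False)
        assert (np.abs(np.diff(with_spike[:, 1])).max()
                > 1.5 * np.abs(np.diff(without[:, 1])).max())


class TestScenario:
    def test_counts_match_annotation_segments(self):
        cfg = ScenarioConfig(counts={"smash": 5, "clear": 3}, displacement_bouts=2, seed=4)
        rec = generate_scenario(cfg)
        segs = []
        labels = rec.labels
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                segs.append(labels[start])
                start = i
        assert segs.count("smash") == 5 and segs.count("clear") == 3
        assert segs.count("displacement") == 2

    def test_default_counts_are_realistic_session(self):
        assert DEFAULT_TEST_COUNTS == {
            "clear": 31, "dab": 30, "drive": 30, "short_serve": 31,
            "lob": 30, "netdrop": 34, "smash": 30,
        }

    def test_zero_counts_pure_rest(self):
        cfg = ScenarioConfig(counts={}, displacement_bouts=0, seed=0)
        rec = generate_scenario(cfg)
        assert set(rec.labels) == {"rest"}

    def test_labels_partition_recording(self):
        cfg = ScenarioConfig(counts={"smash": 3, "lob": 2}, seed=5)
        rec = generate_scenario(cfg)
        assert rec.labels is not None and len(rec.labels) == rec.n_samples
        assert set(rec.labels) <= set(CLASSES)

    def test_full_determinism_under_seed(self):
        cfg = ScenarioConfig(counts={"smash": 3, "clear": 2}, seed=12)
        a, b = generate_scenario(cfg), generate_scenario(cfg)
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_segment_durations_match_templates(self):
        cfg = ScenarioConfig(counts={"clear": 4, "short_serve": 4}, seed=6)
        rec = generate_scenario(cfg)
        labels = rec.labels
        start = 0
        durations = {"clear": [], "short_serve": []}
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                if labels[start] in durations:
                    durations[labels[start]].append((i - start) / rec.fs_hz)
                start = i
        for name, durs in durations.items():
            t = DEFAULT_TEMPLATES[name]
            for d in durs:
                assert abs(d - t.duration_s) <= 5 * t.duration_sd_s + 0.02


class TestConfusabilityStructure:
    def test_drive_clear_accel_similar_gyro_distinct(self):
        """The drive/clear pair shares linear-acceleration structure (RMS per
        accelerometer channel within 5%) while angular rates differ ≥ 3×."""
        drive, clear = DEFAULT_TEMPLATES["drive"], DEFAULT_TEMPLATES["clear"]
        a_d = np.asarray(drive.accel_amp) * np.sqrt(np.mean(np.square(drive.pulse_amps)))
        a_c = np.asarray(clear.accel_amp) * np.sqrt(np.mean(np.square(clear.pulse_amps)))
        assert np.all(np.abs(a_d - a_c) / a_c <= 0.05)
        assert drive.accel_freq == clear.accel_freq
        ratio = np.asarray(clear.gyro_amp) / np.asarray(drive.gyro_amp)
        assert np.all(ratio >= 3.0)

    def test_generated_bursts_reflect_structure(self):
        """On generated data: per-channel peak accelerometer envelope of
        drive vs clear within 5% (analytic-signal amplitude, which is free
        of carrier phase); peak angular-rate envelopes differ ≥ 3×."""
        from scipy.signal import hilbert

        rng = np.random.default_rng(0)
        def mean_envelope_peaks(name):
            acc = np.zeros(3); gyr = np.zeros(3)
            n = 30
            for _ in range(n):
                b = generate_stroke(DEFAULT_TEMPLATES[name], rng)
                env = np.abs(hilbert(b, axis=0))
                acc += env[:, :3].max(axis=0) / n
                gyr += env[:, 3:].max(axis=0) / n
            return acc, gyr
        acc_d, gyr_d = mean_envelope_peaks("drive")
        acc_c, gyr_c = mean_envelope_peaks("clear")
        # 5% template similarity plus slack for the envelope estimator's
        # bias at carriers whose frequency is comparable to the pulse bandwidth
        assert np.all(np.abs(acc_d - acc_c) / acc_c <= 0.10)
        assert np.all(gyr_c / gyr_d >= 3.0)

    def test_duration_ordering_follows_stroke_types(self):
        durs = {n: t.duration_s for n, t in DEFAULT_TEMPLATES.items()}
        assert max(durs, key=durs.get) == "clear" and durs["clear"] == pytest.approx(1.60)
        assert min(durs, key=durs.get) == "short_serve"
        assert durs["smash"] == pytest.approx(0.72)


class TestTwoSubjectSplit:
    def test_zero_jitter_same_vocab_distinct_realizations(self):
        cfg = ScenarioConfig(counts={"smash": 3, "clear": 2}, seed=8)
        train, test = generate_two_subject_split(cfg, subject_jitter=0.0, drill_repeats=2)
        assert train.subject_id == "A" and test.subject_id == "B"
        assert set(train.labels) == set(test.labels) | (set(train.labels) - set(test.labels))
        assert not np.array_equal(train.samples[:100], test.samples[:100])

    def test_train_contains_drill_blocks(self):
        cfg = ScenarioConfig(counts={"smash": 2, "clear": 2}, seed=9)
        train, _ = generate_two_subject_split(cfg, subject_jitter=0.1, drill_repeats=3)
        # drills are successive same-class strokes at the start: the first
        # non-rest segment run should repeat its class back to back
        first_stroke = next(l for l in train.labels if l != "rest")
        idx = np.nonzero(train.labels == first_stroke)[0]
        # at least 3 stroke durations' worth of consecutive same-class samples
        t = DEFAULT_TEMPLATES[first_stroke]
        assert len(idx) >= 3 * 0.8 * t.duration_s * cfg.fs_hz

    def test_negative_jitter_rejected(self):
        with pytest.raises(ValueError):
            generate_two_subject_split(ScenarioConfig(counts={"smash": 1}), -0.1)


def test_left_handed_mirror_inverts_y_channels(small_scenario):
    mirrored = mirror_left_handed(small_scenario)
    np.testing.assert_array_equal(mirrored.samples[:, 1], -small_scenario.samples[:, 1])
    np.testing.assert_array_equal(mirrored.samples[:, 4], -small_scenario.samples[:, 4])
    np.testing.assert_array_equal(mirrored.samples[:, 0], small_scenario.samples[:, 0])
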