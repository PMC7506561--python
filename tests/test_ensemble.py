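import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shuttlesense.ensemble import (
    DEFAULT_BEST_FRAME_SIZES,
    DEFAULT_FRAME_SIZES,
    EnsembleConfig,
    FrameSizeEnsemble,
    align_predictions,
    derive_weights,
    fuse,
    read_weights_csv,
    smooth_predictions,
    train_bank,
    write_fused_csv,
    write_weights_csv,
)
from shuttlesense.models import TrainConfig
from shuttlesense.preprocessing import scale, segment_frames
from shuttlesense.signal_io import CLASSES, IMURecording


class TestFuse:
    def test_single_model_uniform_reduces_to_argmax(self):
        aligned = np.array([[[0.6, 0.4], [0.3, 0.7]]])  # (1, 2, 2)
        idx, conf = fuse(aligned, np.ones((1, 2)))
        np.testing.assert_array_equal(idx, [0, 1])
        np.testing.assert_allclose(conf, [0.6, 0.7])

    def test_weight_flips_decision(self):
        """Direct evaluation of the weighted-certainty rule: (0.6, 0.4) with
        weights (1, 2) scores (0.6, 0.8) and class 1 wins."""
        aligned = np.array([[[0.6, 0.4]]])
        idx, conf = fuse(aligned, np.array([[1.0, 2.0]]))
        assert idx[0] == 1 and conf[0] == pytest.approx(0.8)

    def test_scale_invariance_of_weights(self):
        rng = np.random.default_rng(0)
        aligned = rng.dirichlet(np.ones(5), size=(3, 40)).transpose(0, 1, 2)
        W = rng.uniform(0.1, 2.0, size=(3, 5))
        for combine in ("max", "mean"):
            i1, _ = fuse(aligned, W, combine=combine)
            i2, _ = fuse(aligned, 7.3 * W, combine=combine)
            np.testing.assert_array_equal(i1, i2)

    def test_max_rule_takes_most_confident_model(self):
        aligned = np.array([
            [[0.9, 0.1]],
            [[0.2, 0.8]],
        ])  # model 0 says class 0 at 0.9; model 1 says class 1 at 0.8
        idx, conf = fuse(aligned, combine="max")
        assert idx[0] == 0 and conf[0] == pytest.approx(0.9)
        idx_m, _ = fuse(aligned, combine="mean")  # (0.55, 0.45) → class 0 too
        assert idx_m[0] == 0

    def test_all_zero_weight_column_rejected(self):
        aligned = np.ones((2, 3, 2)) / 2
        with pytest.raises(ValueError, match="all-zero"):
            fuse(aligned, np.array([[1.0, 0.0], [1.0, 0.0]]))

    def test_tie_breaks_to_lowest_class_index(self):
        aligned = np.array([[[0.5, 0.5]]])
        idx, _ = fuse(aligned)
        assert idx[0] == 0


class TestDeriveWeights:
    def test_uniform_all_ones(self):
        W = derive_weights(strategy="uniform")
        np.testing.assert_array_equal(W, np.ones((7, 9)))

    def test_short_serve_peaks_on_smallest_matched_frame(self):
        W = derive_weights(strategy="duration_match")
        col = list(CLASSES).index("short_serve")
        # best 0.68 s → maximal weight on the 0.6 s model
        assert DEFAULT_FRAME_SIZES[np.argmax(W[:, col])] == 0.6

    def test_clear_peaks_on_largest_frame(self):
        W = derive_weights(strategy="duration_match")
        col = list(CLASSES).index("clear")
        assert DEFAULT_FRAME_SIZES[np.argmax(W[:, col])] == 1.6

    def test_neutral_classes_stay_at_one(self):
        W = derive_weights(strategy="duration_match")
        for cls in ("rest", "displacement"):
            np.testing.assert_array_equal(W[:, list(CLASSES).index(cls)], 1.0)

    def test_matched_model_upweighted_relative_to_uniform(self):
        """Duration matching strictly raises a class's score on its best model."""
        W = derive_weights(strategy="duration_match")
        U = derive_weights(strategy="uniform")
        for i, cls in enumerate(CLASSES):
            best = DEFAULT_BEST_FRAME_SIZES[cls]
            if best is None:
                continue
            m = int(np.argmin(np.abs(np.asarray(DEFAULT_FRAME_SIZES) - best)))
            assert W[m, i] > U[m, i]

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown class"):
            derive_weights({"volley": 1.0}, strategy="duration_match")


class TestSmoothing:
    def test_tau_zero_is_identity(self):
        seq = np.array(["a", "b", "a"], dtype=object)
        out = smooth_predictions(seq, np.zeros(3), tau=0.0)
        np.testing.assert_array_equal(out, seq)

    def test_single_dip_takes_flanking_label(self):
        seq = np.array(["smash"] * 3 + ["rest"] + ["smash"] * 3, dtype=object)
        conf = np.array([0.9] * 3 + [0.2] + [0.9] * 3)
        out = smooth_predictions(seq, conf, tau=0.5)
        assert list(out) == ["smash"] * 7

    def test_alternating_low_segment_resolved_by_nearest_with_earlier_ties(self):
        seq = np.array(["a", "x", "y", "x", "b"], dtype=object)
        conf = np.array([0.9, 0.1, 0.1, 0.1, 0.9])
        out = smooth_predictions(seq, conf, tau=0.5)
        # nearest confident: pos1→0, pos2 tie→earlier (0), pos3→4
        assert list(out) == ["a", "a", "a", "b", "b"]

    def test_no_confident_positions_unchanged(self):
        seq = np.array(["a", "b"], dtype=object)
        out = smooth_predictions(seq, np.array([0.1, 0.1]), tau=0.5)
        assert list(out) == ["a", "b"]


@pytest.fixture(scope="module")
def tiny_bank(two_subject_25hz):
    train_rec, _ = two_subject_25hz
    cfg = EnsembleConfig(frame_sizes_s=(0.6, 1.2))
    return train_bank(train_rec, cfg, TrainConfig(epochs=6, val_fraction=0.0, seed=0))


class TestBankAndAlignment:
    def test_one_model_per_frame_size(self, tiny_bank):
        assert len(tiny_bank) == 2
        assert [m.spec_.frame_len for m in tiny_bank] == [15, 30]  # 25 Hz
        assert all(tuple(m.classes_) == CLASSES for m in tiny_bank)

    def test_oversized_frame_rejected(self):
        rec = IMURecording(fs_hz=100, samples=np.zeros((300, 6)),
                          labels=np.array(["rest"] * 150 + ["smash"] * 150, dtype=object))
        cfg = EnsembleConfig(frame_sizes_s=(10.0,))
        with pytest.raises(ValueError, match="zero frames"):
            train_bank(rec, cfg, TrainConfig(epochs=1))

    def test_broadcast_repeats_frame_distribution(self, tiny_bank, two_subject_25hz):
        _, test_rec = two_subject_25hz
        model = tiny_bank[0]
        aligned = align_predictions([model], test_rec)
        L = model.spec_.frame_len
        n_frames = test_rec.n_samples // L
        assert aligned.shape == (1, n_frames * L, len(CLASSES))
        # every sample inside frame i carries frame i's distribution
        for i in (0, n_frames - 1):
            block = aligned[0, i * L : (i + 1) * L]
            assert (block == block[0]).all()
        np.testing.assert_allclose(aligned.sum(axis=2), 1.0, atol=1e-6)

    def test_alignment_grid_length_matches_enumeration(self, tiny_bank, two_subject_25hz):
        _, test_rec = two_subject_25hz
        aligned = align_predictions(tiny_bank, test_rec)
        # brute-force per-sample coverage: grid spans the max coverage,
        # shorter-coverage models pad with their last frame distribution
        coverages = [(test_rec.n_samples // m.spec_.frame_len) * m.spec_.frame_len
                     for m in tiny_bank]
        assert aligned.shape[1] == max(coverages)
        m_short = int(np.argmin(coverages))
        tail = aligned[m_short, coverages[m_short]:]
        if len(tail):
            assert (tail == aligned[m_short, coverages[m_short] - 1]).all()

    def test_identical_models_align_identically(self, tiny_bank, two_subject_25hz):
        _, test_rec = two_subject_25hz
        model = tiny_bank[0]
        aligned = align_predictions([model, model], test_rec)
        np.testing.assert_array_equal(aligned[0], aligned[1])

    def test_single_model_fusion_equals_frame_argmax(self, tiny_bank, two_subject_25hz):
        """Uniform single-model ensemble reproduces the model's own argmax."""
        _, test_rec = two_subject_25hz
        model = tiny_bank[0]
        L = model.spec_.frame_len
        rec = scale(test_rec)
        n = rec.n_samples // L
        probs = model.predict_proba(rec.samples[: n * L].reshape(n, L, 6))
        direct = model.classes_[probs.argmax(axis=1)]
        idx, _ = fuse(align_predictions([model], test_rec))
        fused = model.classes_[idx]
        np.testing.assert_array_equal(fused, np.repeat(direct, L))


class TestEstimator:
    def test_fit_predict_shapes_and_params(self, two_subject_25hz):
        train_rec, test_rec = two_subject_25hz
        ens = FrameSizeEnsemble(frame_sizes=(0.6, 1.2), epochs=4, random_state=0,
                                weights="duration", tau=0.4)
        assert ens.get_params()["frame_sizes"] == (0.6, 1.2)
        ens.fit(train_rec)
        assert len(ens.models_) == 2 and ens.weights_.shape == (2, 9)
        fused = ens.predict_fused(test_rec)
        assert set(fused.labels) <= set(CLASSES)
        assert len(fused.labels) == len(fused.confidences)
        assert 0.0 <= ens.score(test_rec) <= 1.0


class TestWeightIO:
    def test_weights_csv_round_trip(self, tmp_path):
        W = derive_weights(strategy="duration_match")
        write_weights_csv(tmp_path / "w.csv", W)
        back, sizes, vocab = read_weights_csv(tmp_path / "w.csv")
        np.testing.assert_allclose(back, W, atol=1e-6)
        assert tuple(vocab) == CLASSES and tuple(sizes) == DEFAULT_FRAME_SIZES

    def test_fused_csv_run_length_encoding(self, tmp_path):
        from shuttlesense.ensemble import FusedPrediction

        fused = FusedPrediction(
            labels=np.array(["rest"] * 10 + ["smash"] * 5, dtype=object),
            confidences=np.linspace(0.5, 1.0, 15),
            fs_hz=100.0,
            class_vocab=CLASSES,
        )
        write_fused_csv(tmp_path / "fused.csv", fused)
        lines = (tmp_path / "fused.csv").read_text().strip().splitlines()
        assert lines[0] == "start_s,end_s,label,confidence"
        assert len(lines) == 3  # header + 2 runs
        assert lines[1].split(",")[2] == "rest" and lines[2].split(",")[2] == "smash"
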