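"""Backbone construction, loss, F1, training-loop selection semantics."""

import dataclasses

import numpy as np
import pytest

from igcbir import backbone as B
from igcbir import nn, phantoms


class TestBuild:
    def test_densenet121_penultimate_width(self):
        m = B.build_backbone("densenet121")
        assert m.feature_dim == 1024

    def test_tiny_default_feature_dim(self):
        m = B.build_backbone("tiny", (96, 96, 1))
        assert m.feature_dim == 64

    def test_tiny_forward_probability(self, rng):
        m = B.build_backbone("tiny", (32, 32, 1))
        p = m.predict_proba(rng.uniform(0, 1, (3, 1, 32, 32)).astype(np.float32))
        assert p.shape == (3,) and np.all((p > 0) & (p < 1))

    def test_degenerate_input_spec_rejected(self):
        with pytest.raises(B.ArchitectureError):
            B.build_backbone("tiny", (96, 96, 0))
        with pytest.raises(B.ArchitectureError):
            B.build_backbone("nope")


class TestWeightedBce:
    def test_perfect_prediction_zero_loss(self):
        assert B.weighted_bce(1, 1.0 - 1e-9) < 1e-5

    def test_uniform_prediction_ln2(self):
        assert B.weighted_bce(0, 0.5) == pytest.approx(np.log(2), rel=1e-9)

    def test_inverse_frequency_weights_hand_arithmetic(self):
        # 90 negatives, 10 positives: w = N/(2 N_c) -> (100/180, 100/20)
        labels = np.array([0] * 90 + [1] * 10)
        w = B.class_weights(labels)
        assert w == pytest.approx((100 / 180, 100 / 20))
        assert w[1] / w[0] == pytest.approx(9.0)
        # mixed batch against hand arithmetic
        y = np.array([1, 0, 0])
        p = np.array([0.8, 0.3, 0.6])
        expected = (-w[1] * np.log(0.8) - w[0] * np.log(0.7) - w[0] * np.log(0.4)) / 3
        assert B.weighted_bce(y, p, w) == pytest.approx(expected, rel=1e-12)

    def test_positive_and_zero_only_at_perfect(self, rng):
        y = rng.integers(0, 2, 50)
        p = rng.uniform(0.01, 0.99, 50)
        assert B.weighted_bce(y, p) > 0

    def test_nonbinary_label_rejected(self):
        with pytest.raises(ValueError):
            B.weighted_bce(0.5, 0.5)

    def test_single_class_weighting_rejected(self):
        with pytest.raises(B.WeightingError):
            B.class_weights(np.ones(10))


class TestF1:
    def test_all_correct(self):
        assert B.f1_score(np.array([0.9, 0.1]), np.array([1, 0])) == 1.0

    def test_hand_cases(self):
        # TP=8 FP=2 FN=2 -> 0.8 ; TP=3 FP=1 FN=2 -> 0.6667
        preds = np.array([0.9] * 8 + [0.9] * 2 + [0.1] * 2)
        labels = np.array([1] * 8 + [0] * 2 + [1] * 2)
        assert B.f1_score(preds, labels) == pytest.approx(0.8)
        preds = np.array([0.9] * 3 + [0.9] + [0.1] * 2)
        labels = np.array([1] * 3 + [0] + [1] * 2)
        assert B.f1_score(preds, labels) == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_confusion_matrix_oracle_equivalence(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 40))
            preds = rng.uniform(0, 1, n)
            labels = rng.integers(0, 2, n)
            yhat = preds >= 0.5
            tp = int(np.sum(yhat & (labels == 1)))
            fp = int(np.sum(yhat & (labels == 0)))
            fn = int(np.sum(~yhat & (labels == 1)))
            oracle = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
            assert B.f1_score(preds, labels) == pytest.approx(oracle, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            B.f1_score(np.array([]), np.array([]))


@pytest.fixture(scope="module")
def micro_data():
    cfg = phantoms.PhantomConfig(image_size=32, seed=5)
    samples = phantoms.generate_dataset(cfg, 40)
    return samples[:28], samples[28:]


@pytest.fixture(scope="module")
def micro_tc():
    return B.TrainConfig(epochs=2, batch_size=8, optimizer="adam",
                         learning_rate=1e-3, seed=9)


class TestTrain:
    def test_single_epoch_selected(self, micro_data, micro_tc):
        tr, va = micro_data
        m = B.build_backbone("tiny", (32, 32, 1), seed=0)
        _, log = B.train(m, tr, va, dataclasses.replace(micro_tc, epochs=1))
        assert log.selected_epoch == 1
        assert log.records["selected"].sum() == 1

    def test_selection_is_argmax_earliest(self, micro_data, micro_tc):
        tr, va = micro_data
        m = B.build_backbone("tiny", (32, 32, 1), seed=0)
        _, log = B.train(m, tr, va, micro_tc)
        f1s = log.records["val_f1"].to_numpy()
        assert log.selected_epoch == int(np.argmax(f1s)) + 1
        assert f1s[log.selected_epoch - 1] >= f1s.max() - 1e-12

    def test_seed_invariance(self, micro_data, micro_tc):
        tr, va = micro_data
        logs = []
        for _ in range(2):
            m = B.build_backbone("tiny", (32, 32, 1), seed=3)
            _, log = B.train(m, tr, va, micro_tc)
            logs.append(log.records)
        assert logs[0].equals(logs[1])

    def test_warm_start_and_shape_mismatch(self, micro_data, micro_tc, tmp_path):
        tr, va = micro_data
        donor = B.build_backbone("tiny", (32, 32, 1), seed=1)
        donor.save(tmp_path / "donor")
        m = B.build_backbone("tiny", (32, 32, 1), seed=2)
        cfg = dataclasses.replace(micro_tc, epochs=1, init_from=tmp_path / "donor")
        _, log = B.train(m, tr, va, cfg)
        assert log.init_fingerprint == donor.fingerprint()
        other = B.build_backbone("tiny", (32, 32, 1), feature_dim=16, seed=0)
        with pytest.raises(B.CheckpointError):
            B.train(other, tr, va, cfg)

    def test_checkpoint_round_trip(self, micro_data, tmp_path):
        m = B.build_backbone("tiny", (32, 32, 1), seed=4)
        m.save(tmp_path / "m")
        m2 = B.load_checkpoint(tmp_path / "m")
        x = np.random.default_rng(0).uniform(0, 1, (32, 32))
        assert np.array_equal(B.extract_features(m, x), B.extract_features(m2, x))


class TestFeatures:
    def test_deterministic_and_length(self):
        m = B.build_backbone("tiny", (32, 32, 1))
        x = np.random.default_rng(1).uniform(0, 1, (32, 32))
        f1 = B.extract_features(m, x)
        f2 = B.extract_features(m, x)
        assert f1.shape == (64,)
        assert np.array_equal(f1, f2)

    def test_shape_mismatch_rejected(self):
        m = B.build_backbone("tiny", (32, 32, 1))
        with pytest.raises(ValueError):
            B.extract_features(m, np.zeros((16, 16)))


def test_benchmark_classifier_reaches_high_f1(bench):
    """On default phantoms the tiny classifier separates the classes well."""
    assert bench.logs["cnn"].records["val_f1"].max() >= 0.9


def test_selected_model_matches_best_epoch(bench):
    for name, log in bench.logs.items():
        sel = log.records.loc[log.records["selected"], "val_f1"].item()
        assert sel >= log.records["val_f1"].max() - 1e-12
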