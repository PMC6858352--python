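import numpy as np
import pytest

from fluoromap.classifier import (ConstantClassifier, NoisyOracleConfig,
                                  TrainConfig, evaluate_patches, noisy_oracle,
                                  train_small_cnn)
from fluoromap.classifier.base import PatchClassifier
from fluoromap.classifier.smallcnn import SmallCNNClassifier, select_checkpoint
from fluoromap.mapper import MapperConfig, build_map, ground_truth_map
from fluoromap.patches import NEGATIVE, POSITIVE, PatchRecord

from conftest import make_blank_image


def make_toy_records(rng, label, n, bright, size=32):
    """Toy patches separable by a mean-green-intensity threshold oracle."""
    records = []
    for _ in range(n):
        pixels = rng.random((size, size, 3)) * 0.2
        if bright:
            pixels[..., 1] += 0.6
        pixels /= pixels.max()
        records.append(PatchRecord(
            pixels=pixels, grid_row=0, grid_col=0, source_image="toy",
            label=label, tumor_fraction=1.0 if label == POSITIVE else 0.0))
    return records


def mean_green_oracle_accuracy(records, threshold=0.7):
    """Independent oracle: classify by mean green intensity alone."""
    correct = 0
    for rec in records:
        pred = POSITIVE if rec.pixels[..., 1].mean() > threshold else NEGATIVE
        correct += pred == rec.label
    return correct / len(records)


class _ScriptedClassifier(PatchClassifier):
    """Reads its output from the patch's top-left pixel (test probe)."""

    def predict_proba(self, patch, pos=None) -> float:
        return float(patch[0, 0, 0])


class TestContract:
    def test_constant_classifier_bounds(self):
        with pytest.raises(ValueError):
            ConstantClassifier(1.5)
        assert ConstantClassifier(0.3).predict_proba(None) == 0.3

    def test_probability_bounds_on_trained_model(self):
        rng = np.random.default_rng(0)
        train = (make_toy_records(rng, POSITIVE, 6, True)
                 + make_toy_records(rng, NEGATIVE, 6, False))
        val = (make_toy_records(rng, POSITIVE, 2, True)
               + make_toy_records(rng, NEGATIVE, 2, False))
        model = train_small_cnn(train, val, TrainConfig(
            phase1_epochs=2, phase2_epochs=1, seed=0))
        for rec in val:
            p = model.predict_proba(rec.pixels)
            assert 0.0 <= p <= 1.0


class TestCheckpointPolicy:
    def test_argmin_selection(self):
        # losses [0.50, 0.30, 0.40] -> checkpoint from epoch 2 (index 1)
        assert select_checkpoint([0.50, 0.30, 0.40]) == 1

    def test_empty_history(self):
        with pytest.raises(ValueError):
            select_checkpoint([])

    def test_returned_state_is_best_epoch(self):
        rng = np.random.default_rng(1)
        train = (make_toy_records(rng, POSITIVE, 8, True)
                 + make_toy_records(rng, NEGATIVE, 8, False))
        val = (make_toy_records(rng, POSITIVE, 3, True)
               + make_toy_records(rng, NEGATIVE, 3, False))
        model = train_small_cnn(train, val, TrainConfig(
            phase1_epochs=4, phase2_epochs=2, seed=0))
        losses = model.validation_losses
        assert losses[model.best_epoch] == min(losses)


class TestTrainSmallCNN:
    def test_separable_toy_problem(self):
        rng = np.random.default_rng(7)
        train = (make_toy_records(rng, POSITIVE, 16, True)
                 + make_toy_records(rng, NEGATIVE, 16, False))
        val = (make_toy_records(rng, POSITIVE, 6, True)
               + make_toy_records(rng, NEGATIVE, 6, False))
        test = (make_toy_records(rng, POSITIVE, 10, True)
                + make_toy_records(rng, NEGATIVE, 10, False))
        # sanity: the independent mean-intensity oracle achieves 1.0
        assert mean_green_oracle_accuracy(test) == 1.0
        model = train_small_cnn(train, val, TrainConfig(
            phase1_epochs=6, phase2_epochs=4, seed=0))
        metrics = evaluate_patches(model, test)
        assert metrics.accuracy > 0.95

    def test_single_class_train_rejected(self):
        rng = np.random.default_rng(0)
        train = make_toy_records(rng, POSITIVE, 4, True)
        val = make_toy_records(rng, POSITIVE, 2, True)
        with pytest.raises(ValueError):
            train_small_cnn(train, val, TrainConfig(seed=0))

    def test_empty_validation_rejected(self):
        rng = np.random.default_rng(0)
        train = (make_toy_records(rng, POSITIVE, 2, True)
                 + make_toy_records(rng, NEGATIVE, 2, False))
        with pytest.raises(ValueError):
            train_small_cnn(train, [], TrainConfig(seed=0))

    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(3)
        train = (make_toy_records(rng, POSITIVE, 4, True)
                 + make_toy_records(rng, NEGATIVE, 4, False))
        val = train[:4]
        model = train_small_cnn(train, val, TrainConfig(
            phase1_epochs=2, phase2_epochs=1, seed=0))
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = SmallCNNClassifier.load(path)
        for rec in val:
            assert loaded.predict_proba(rec.pixels) == pytest.approx(
                model.predict_proba(rec.pixels))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(dropout=1.0)
        with pytest.raises(ValueError):
            TrainConfig(phase1_epochs=0)


class TestNoisyOracle:
    def test_zero_rates_equal_ground_truth(self, small_positive_image):
        config = MapperConfig(patch_size=64, step=16)
        clf = noisy_oracle(small_positive_image, NoisyOracleConfig(0, 0, 5))
        pmap = build_map(small_positive_image, clf, config)
        truth = ground_truth_map(small_positive_image, config)
        assert np.array_equal(pmap.grid, truth.grid)
        assert pmap.grid.any()  # the lesion is visible in the map

    def test_fp_one_all_positive(self):
        image = make_blank_image(200, 200)
        config = MapperConfig(patch_size=64, step=16)
        clf = noisy_oracle(image, NoisyOracleConfig(fp_rate=1.0, seed=0))
        pmap = build_map(image, clf, config)
        assert (pmap.grid == 1).all()

    def test_deterministic_per_seed_and_position(self):
        image = make_blank_image(200, 200)
        config = MapperConfig(patch_size=64, step=16)
        clf = noisy_oracle(image, NoisyOracleConfig(fp_rate=0.5, seed=9))
        a = build_map(image, clf, config)
        b = build_map(image, clf, config)
        assert np.array_equal(a.grid, b.grid)

    def test_fast_and_loop_paths_agree(self, small_positive_image):
        config = MapperConfig(patch_size=64, step=16)
        clf = noisy_oracle(small_positive_image,
                           NoisyOracleConfig(0.3, 0.2, seed=21))
        fast = build_map(small_positive_image, clf, config)
        loop = build_map(small_positive_image, clf, config,
                         use_fast_path=False)
        assert np.array_equal(fast.grid, loop.grid)

    def test_requires_position(self, small_positive_image):
        clf = noisy_oracle(small_positive_image, NoisyOracleConfig(0, 0, 0))
        with pytest.raises(ValueError):
            clf.predict_proba(np.zeros((4, 4, 3)))

    def test_error_counts_binomial(self):
        # empirical FP count mean over >=30 seeds within 3 binomial SEs
        image = make_blank_image(300, 300)
        config = MapperConfig(patch_size=64, step=8)
        fp_rate = 0.05
        counts = []
        for seed in range(40):
            clf = noisy_oracle(image, NoisyOracleConfig(fp_rate, 0, seed))
            counts.append(int(build_map(image, clf, config).grid.sum()))
        n_windows = build_map(
            image, noisy_oracle(image, NoisyOracleConfig(0, 0, 0)),
            config).n_predictions
        expected = n_windows * fp_rate
        se = np.sqrt(n_windows * fp_rate * (1 - fp_rate) / len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_rate_validation(self):
        with pytest.raises(ValueError):
            NoisyOracleConfig(fp_rate=1.2)


class TestEvaluatePatches:
    def test_perfect_oracle_metrics(self):
        rng = np.random.default_rng(11)
        records = (make_toy_records(rng, POSITIVE, 5, True)
                   + make_toy_records(rng, NEGATIVE, 5, False))

        class Perfect(PatchClassifier):
            def predict_proba(self, patch, pos=None):
                return 1.0 if patch[..., 1].mean() > 0.7 else 0.0

        metrics = evaluate_patches(Perfect(), records)
        assert metrics.accuracy == 1.0
        assert metrics.auc == 1.0

    def test_constant_half_ties_to_positive(self):
        rng = np.random.default_rng(2)
        records = (make_toy_records(rng, POSITIVE, 5, True)
                   + make_toy_records(rng, NEGATIVE, 5, False))
        metrics = evaluate_patches(ConstantClassifier(0.5), records)
        # p >= 0.5 is a positive call: all positives right, negatives wrong
        assert metrics.accuracy == 0.5
        assert metrics.tp == 5 and metrics.fp == 5

    def test_reported_error_arithmetic(self):
        # 1,843 + 1,987 = 3,830 patches with 28 FP and 19 FN
        rng = np.random.default_rng(4)
        records, probs = [], []
        for label, n_correct, n_wrong in ((POSITIVE, 1843 - 19, 19),
                                          (NEGATIVE, 1987 - 28, 28)):
            is_pos = label == POSITIVE
            for i in range(n_correct + n_wrong):
                wrong = i < n_wrong
                p = (0.0 if is_pos else 1.0) if wrong \
                    else (1.0 if is_pos else 0.0)
                pixels = np.full((2, 2, 3), p)
                records.append(PatchRecord(
                    pixels=pixels, grid_row=0, grid_col=0, source_image="x",
                    label=label, tumor_fraction=1.0 if is_pos else 0.0))
        metrics = evaluate_patches(_ScriptedClassifier(), records)
        assert metrics.total == 3830
        assert metrics.fp == 28 and metrics.fn == 19
        assert metrics.accuracy == pytest.approx((3830 - 47) / 3830)
        assert metrics.accuracy == pytest.approx(0.9877, abs=5e-5)

    def test_confusion_counts_permutation_invariant(self):
        rng = np.random.default_rng(8)
        records = (make_toy_records(rng, POSITIVE, 6, True)
                   + make_toy_records(rng, NEGATIVE, 6, False))
        clf = _ScriptedClassifier()
        base = evaluate_patches(clf, records)
        shuffled = list(records)
        rng.shuffle(shuffled)
        perm = evaluate_patches(clf, shuffled)
        assert (base.tp, base.fp, base.tn, base.fn) == \
            (perm.tp, perm.fp, perm.tn, perm.fn)

    def test_single_class_auc_absent(self):
        rng = np.random.default_rng(5)
        records = make_toy_records(rng, POSITIVE, 4, True)
        metrics = evaluate_patches(ConstantClassifier(1.0), records)
        assert metrics.auc is None
        assert metrics.roc_points is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            evaluate_patches(ConstantClassifier(0.5), [])
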