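"""Dataset splitting, metrics, fine-tuning mechanics."""

import hashlib

import numpy as np
import pytest

from csvfilt.augment import AugmentConfig
from csvfilt.model import CLASS_ORDER, ModelConfig, SVClassifier
from csvfilt.training import TrainConfig, compute_metrics, evaluate, finetune, split_dataset

rng = np.random.default_rng(0)


def brute_force_macro_f1(y_true, y_pred):
    """Independent recomputation from the confusion matrix definition."""
    f1s = []
    for c in CLASS_ORDER:
        tp = np.sum((y_true == c) & (y_pred == c))
        fp = np.sum((y_true != c) & (y_pred == c))
        fn = np.sum((y_true == c) & (y_pred != c))
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1s.append(2 * p * r / (p + r) if p + r else 0.0)
    return float(np.mean(f1s))


class TestSplitDataset:
    def test_80_10_10_sizes(self):
        labels = ["INS"] * 40 + ["DEL"] * 30 + ["NEG"] * 30
        tr, va, te = split_dataset(labels, (0.8, 0.1, 0.1), seed=0)
        assert (len(tr), len(va), len(te)) == (80, 10, 10)

    def test_partition_and_stratification(self):
        labels = np.array(["INS"] * 50 + ["DEL"] * 30 + ["NEG"] * 20)
        tr, va, te = split_dataset(labels, seed=1)
        allidx = np.concatenate([tr, va, te])
        assert sorted(allidx) == list(range(100))
        assert len(set(tr) & set(va)) == 0 and len(set(va) & set(te)) == 0
        # per-class proportions preserved in the training part
        assert np.sum(labels[tr] == "INS") == 40

    def test_reproducible(self):
        labels = ["INS"] * 10 + ["DEL"] * 10 + ["NEG"] * 10
        a = split_dataset(labels, seed=7)
        b = split_dataset(labels, seed=7)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(["INS"] * 10 + ["DEL"] * 2, seed=0)


class TestComputeMetrics:
    def test_perfect_predictions(self):
        y = np.array(["INS", "DEL", "NEG"] * 10)
        report = compute_metrics(y, y.copy(), probs=_onehot(y))
        assert report.accuracy == 1.0 and report.macro_f1 == 1.0
        assert all(v["auc"] == 1.0 for v in report.roc.values())

    def test_constant_predictor_on_balanced_data(self):
        y = np.array(["INS", "DEL", "NEG"] * 10)
        pred = np.array(["NEG"] * 30)
        report = compute_metrics(y, pred)
        assert report.accuracy == pytest.approx(1 / 3)

    def test_confusion_trace_equals_correct_count(self):
        y = rng.choice(CLASS_ORDER, size=100)
        pred = rng.choice(CLASS_ORDER, size=100)
        report = compute_metrics(y, pred)
        assert np.trace(report.confusion) == np.sum(y == pred)
        assert report.confusion.sum(axis=1).tolist() == \
            [np.sum(y == c) for c in CLASS_ORDER]

    def test_macro_f1_matches_brute_force_oracle(self):
        for _ in range(200):
            y = np.concatenate([np.array(CLASS_ORDER), rng.choice(CLASS_ORDER, size=27)])
            pred = rng.choice(CLASS_ORDER, size=30)
            assert compute_metrics(y, pred).macro_f1 == \
                pytest.approx(brute_force_macro_f1(y, pred), rel=1e-12)

    def test_absent_class_excluded_with_warning(self):
        y = np.array(["INS", "DEL"] * 5)
        pred = np.array(["INS"] * 10)
        with pytest.warns(UserWarning, match="absent"):
            report = compute_metrics(y, pred)
        assert np.isnan(report.per_class["NEG"]["f1"])
        assert not np.isnan(report.macro_f1)


def _onehot(y):
    return np.stack([(y == c).astype(float) for c in CLASS_ORDER], axis=1)


def _toy_images(n_per_class=8):
    """Trivially separable synthetic canvases: one level per class."""
    images, labels = [], []
    for level, label in ((63, "INS"), (191, "DEL"), (0, "NEG")):
        for i in range(n_per_class):
            img = np.zeros((224, 224), dtype=np.uint8)
            img[:, 50:150] = level
            img[i, 0] = 1  # break exact duplicates
            images.append(img)
            labels.append(label)
    return np.stack(images), np.array(labels)


class TestFinetune:
    def test_freezing_keeps_weights_bit_identical(self):
        images, labels = _toy_images(4)
        model = SVClassifier(ModelConfig(rng_seed=0))
        before = hashlib.sha256(
            b"".join(p.data.tobytes() for n, p in sorted(model.parameters().items())
                     if n.startswith("backbone."))).hexdigest()
        cfg = TrainConfig(epochs=1, rng_seed=0, freeze_layers=("backbone.",))
        model, _ = finetune(model, images, labels, images, labels, cfg)
        after = hashlib.sha256(
            b"".join(p.data.tobytes() for n, p in sorted(model.parameters().items())
                     if n.startswith("backbone."))).hexdigest()
        assert before == after

    def test_loss_decreases_and_fits_separable_data(self):
        images, labels = _toy_images(8)
        model = SVClassifier(ModelConfig(rng_seed=1))
        cfg = TrainConfig(epochs=6, rng_seed=1)
        model, history = finetune(model, images, labels, images, labels, cfg)
        assert history[-1]["train_loss"] < history[0]["train_loss"]
        report = evaluate(model, images, labels)
        assert report.macro_f1 == 1.0

    def test_mixed_precision_close_to_full_precision(self):
        images, labels = _toy_images(6)
        scores = []
        for mp in (False, True):
            model = SVClassifier(ModelConfig(rng_seed=2))
            cfg = TrainConfig(epochs=5, rng_seed=2, mixed_precision=mp)
            model, _ = finetune(model, images, labels, images, labels, cfg)
            scores.append(evaluate(model, images, labels).macro_f1)
        assert abs(scores[0] - scores[1]) < 0.02

    def test_empty_train_set_rejected(self):
        model = SVClassifier(ModelConfig(rng_seed=0))
        with pytest.raises(ValueError):
            finetune(model, np.zeros((0, 224, 224), dtype=np.uint8), [],
                     np.zeros((0, 224, 224), dtype=np.uint8), [], TrainConfig(epochs=1))

    def test_evaluation_requires_eval_mode(self):
        images, labels = _toy_images(4)
        model = SVClassifier(ModelConfig(rng_seed=0))
        with pytest.raises(ValueError):
            evaluate(model, images, labels, AugmentConfig(train_mode=True))
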