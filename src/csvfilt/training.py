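"""Supervised training, dataset splitting and evaluation metrics.

Fine-tunes the classifier with cross-entropy under Adam, optionally
starting from a self-supervised checkpoint and freezing chosen layers.
Data are split 80/10/10 (train/validation/test) stratified by label; the
best model is selected by validation macro-F1, matching the
macro-averaged precision/recall/F1 reporting used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
    roc_auc_score,
    roc_curve,
)

from .augment import AugmentConfig, prepare
from .autodiff import Adam, Tensor, softmax_cross_entropy
from .model import CLASS_INDEX, CLASS_ORDER, SVClassifier


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 10
    batch_size: int = 16
    learning_rate: float = 3e-3
    optimizer: str = "adam"
    freeze_layers: tuple[str, ...] = ()
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    rng_seed: int = 0
    mixed_precision: bool = False

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class MetricsReport:
    per_class: dict[str, dict[str, float]]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float
    confusion: np.ndarray  # rows: true class, cols: predicted, in CLASS_ORDER
    roc: dict[str, dict] = field(default_factory=dict)  # per-class one-vs-rest

    def to_dict(self) -> dict:
        return {
            "per_class": self.per_class,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "roc": {c: {"auc": v["auc"]} for c, v in self.roc.items()},
        }


def split_dataset(labels, fractions=(0.8, 0.1, 0.1), seed: int = 0):
    """Stratified train/val/test index split, reproducible by seed.

    Returns three disjoint integer index arrays whose union covers the
    input.  Every class must have at least 3 members so each part can be
    represented.
    """
    labels = np.asarray(labels)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    parts: tuple[list[int], list[int], list[int]] = ([], [], [])
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 3:
            raise ValueError(f"class {cls!r} has only {idx.size} members; need >= 3")
        idx = rng.permutation(idx)
        n = idx.size
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        n_train = min(n_train, n - 2)
        n_val = max(1, min(n_val, n - n_train - 1))
        parts[0].extend(idx[:n_train])
        parts[1].extend(idx[n_train:n_train + n_val])
        parts[2].extend(idx[n_train + n_val:])
    return tuple(np.sort(np.array(p, dtype=np.int64)) for p in parts)


def compute_metrics(y_true, y_pred, probs: np.ndarray | None = None) -> MetricsReport:
    """Per-class and macro P/R/F1, accuracy, confusion matrix, optional ROC/AUC.

    ``y_true``/``y_pred`` are label strings from CLASS_ORDER.  A class
    absent from ``y_true`` is reported as undefined (NaN) and excluded
    from the macro averages with a warning.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    labels = list(CLASS_ORDER)
    present = [c for c in labels if np.any(y_true == c)]
    absent = [c for c in labels if c not in present]
    if absent:
        warnings.warn(f"classes absent from the test set: {absent}; excluded from macro averages")
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average=None, zero_division=0
    )
    per_class = {}
    for i, c in enumerate(labels):
        if c in present:
            per_class[c] = {"precision": float(prec[i]), "recall": float(rec[i]),
                            "f1": float(f1[i]), "support": int(support[i])}
        else:
            per_class[c] = {"precision": float("nan"), "recall": float("nan"),
                            "f1": float("nan"), "support": 0}
    keep = [labels.index(c) for c in present]
    report = MetricsReport(
        per_class=per_class,
        macro_precision=float(np.mean(prec[keep])),
        macro_recall=float(np.mean(rec[keep])),
        macro_f1=float(np.mean(f1[keep])),
        accuracy=float(accuracy_score(y_true, y_pred)),
        confusion=confusion_matrix(y_true, y_pred, labels=labels),
    )
    if probs is not None:
        probs = np.asarray(probs)
        for i, c in enumerate(labels):
            y_bin = (y_true == c).astype(int)
            if c not in present or len(np.unique(y_bin)) < 2:
                continue
            fpr, tpr, _ = roc_curve(y_bin, probs[:, i])
            report.roc[c] = {"fpr": fpr.tolist(), "tpr": tpr.tolist(),
                             "auc": float(roc_auc_score(y_bin, probs[:, i]))}
    return report


def _prepare_batch(images: np.ndarray, idx, aug_cfg: AugmentConfig,
                   rng: np.random.Generator | None) -> np.ndarray:
    return np.stack([prepare(images[i], aug_cfg, rng) for i in idx])


def evaluate(model: SVClassifier, images: np.ndarray, labels,
             aug_cfg: AugmentConfig | None = None, batch_size: int = 32) -> MetricsReport:
    """Deterministic evaluation (no jitter) of a labeled image set."""
    aug_cfg = aug_cfg or AugmentConfig(train_mode=False)
    if aug_cfg.train_mode:
        raise ValueError("evaluation must run with train_mode=False")
    labels = np.asarray(labels)
    probs = []
    for start in range(0, len(images), batch_size):
        idx = range(start, min(start + batch_size, len(images)))
        probs.append(model.forward_probs(_prepare_batch(images, idx, aug_cfg, None)))
    probs = np.concatenate(probs) if probs else np.zeros((0, 3))
    preds = np.array([CLASS_ORDER[i] for i in probs.argmax(axis=1)])
    return compute_metrics(labels, preds, probs)


def finetune(
    model: SVClassifier,
    train_images: np.ndarray, train_labels,
    val_images: np.ndarray, val_labels,
    cfg: TrainConfig | None = None,
    aug_cfg: AugmentConfig | None = None,
):
    """Cross-entropy fine-tuning with best-validation-macro-F1 model selection.

    ``cfg.freeze_layers`` holds parameter-name prefixes (e.g. "backbone.")
    whose weights receive no updates.  Returns the model (weights set to
    the best-validation state) and a per-epoch history list.
    """
    cfg = cfg or TrainConfig()
    if len(train_images) == 0:
        raise ValueError("empty training set")
    aug_train = aug_cfg or AugmentConfig(train_mode=True)
    aug_eval = AugmentConfig(**{**{f: getattr(aug_train, f) for f in aug_train.__dataclass_fields__},
                                "train_mode": False})
    rng = np.random.default_rng(cfg.rng_seed)
    y_train = np.array([CLASS_INDEX[l] for l in train_labels])
    params = model.parameters()
    frozen = {name for name in params
              if any(name.startswith(pref) for pref in cfg.freeze_layers)}
    opt = Adam(params, lr=cfg.learning_rate, frozen=frozen)
    model.mixed_precision = cfg.mixed_precision

    best_f1, best_state = -1.0, None
    history = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_images))
        total_loss, n_batches = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = _prepare_batch(train_images, idx, aug_train, rng)
            loss = softmax_cross_entropy(model.logits(Tensor(batch)), y_train[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            total_loss += float(loss.data)
            n_batches += 1
        val_report = evaluate(model, val_images, val_labels, aug_eval)
        history.append({"epoch": epoch, "train_loss": total_loss / max(n_batches, 1),
                        "val_macro_f1": val_report.macro_f1,
                        "val_accuracy": val_report.accuracy})
        if val_report.macro_f1 > best_f1:
            best_f1 = val_report.macro_f1
            best_state = {k: p.data.copy() for k, p in params.items()}
    if best_state is not None:
        for k, p in params.items():
            p.data = best_state[k]
    return model, history


__all__ = [
    "TrainConfig", "MetricsReport", "split_dataset", "compute_metrics",
    "evaluate", "finetune",
]
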