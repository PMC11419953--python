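"""SV classifier: compact convolutional backbone + attention FC residual head.

The head follows the construction used for CIGAR-image classification:
two attention fully-connected units (per-feature sigmoid gating, affine
map, ReLU) and one plain fully-connected unit, wrapped in a residual skip
connection, followed by an affine map to three logits and a softmax over
{INS, DEL, NEG}.

The built-in backbones are small CNNs designed to train in minutes on a
CPU; the classic ImageNet backbone names are recognized but require an
external deep-learning framework and are rejected with a clear error.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, avg_pool2d, conv2d, softmax
from .encoder import GrayscaleMap

CLASS_ORDER = ("INS", "DEL", "NEG")
CLASS_INDEX = {c: i for i, c in enumerate(CLASS_ORDER)}

_BUILTIN_BACKBONES = ("tiny_cnn", "tiny_cnn_wide")
_EXTERNAL_BACKBONES = ("resnet34", "resnet50", "resnet50x2", "resnet200x2", "mobilenet_v2")


@dataclass(frozen=True)
class ModelConfig:
    backbone: str = "tiny_cnn"
    embed_dim: int = 32
    head_hidden: int = 32
    n_classes: int = 3
    pretrained_source: str = "none"  # none | ssl_checkpoint
    mixed_precision: bool = False
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_classes != 3:
            raise ValueError("the classifier is a 3-class model (INS/DEL/NEG)")
        if self.embed_dim <= 0:
            raise ValueError("embed_dim must be positive")
        if self.backbone in _EXTERNAL_BACKBONES:
            raise ValueError(
                f"backbone {self.backbone!r} requires an external deep-learning "
                f"framework; the built-in backbones are {_BUILTIN_BACKBONES}"
            )
        if self.backbone not in _BUILTIN_BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.pretrained_source not in ("none", "ssl_checkpoint"):
            raise ValueError("pretrained_source must be 'none' or 'ssl_checkpoint'")


@dataclass(frozen=True)
class ClassProbabilities:
    p_ins: float
    p_del: float
    p_neg: float

    def __post_init__(self):
        vec = self.as_array()
        if np.any(vec < -1e-9) or np.any(vec > 1 + 1e-9) or abs(vec.sum() - 1) > 1e-6:
            raise ValueError(f"invalid probability vector {vec}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_ins, self.p_del, self.p_neg], dtype=np.float64)


def predict_label(p: ClassProbabilities) -> str:
    """Highest-probability class; ties broken by the fixed order INS < DEL < NEG."""
    return CLASS_ORDER[int(np.argmax(p.as_array()))]


# ---------------------------------------------------------------------------
# layers

class _Module:
    """Tiny layer base: parameters registered in a flat name -> Tensor dict."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "_Module"] = {}

    def add_param(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array.astype(np.float32), requires_grad=True)
        self._params[name] = t
        return t

    def add_child(self, name: str, module: "_Module") -> "_Module":
        self._children[name] = module
        return module

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, child in self._children.items():
            out.update(child.parameters(prefix=f"{prefix}{name}."))
        return out


class Linear(_Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, zero: bool = False):
        super().__init__()
        scale = 0.0 if zero else float(np.sqrt(2.0 / d_in))
        self.w = self.add_param("w", rng.normal(0.0, scale, size=(d_in, d_out)) if scale else np.zeros((d_in, d_out)))
        self.b = self.add_param("b", np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv(_Module):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int, padding: int,
                 rng: np.random.Generator):
        super().__init__()
        scale = float(np.sqrt(2.0 / (c_in * k * k)))
        self.w = self.add_param("w", rng.normal(0.0, scale, size=(c_out, c_in, k, k)))
        self.b = self.add_param("b", np.zeros(c_out))
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class AttentionFCUnit(_Module):
    """Attention operation (per-feature sigmoid gate), affine map, ReLU."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.gate = self.add_child("gate", Linear(d_in, d_in, rng))
        self.fc = self.add_child("fc", Linear(d_in, d_out, rng))

    def __call__(self, x: Tensor) -> Tensor:
        gated = x * self.gate(x).sigmoid()
        return self.fc(gated).relu()


class FCUnit(_Module):
    """Affine map followed by ReLU."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.fc = self.add_child("fc", Linear(d_in, d_out, rng))

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc(x).relu()


class AttentionResidualModule(_Module):
    """Two attention FC units + one FC unit, with a skip over the whole stack."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.a1 = self.add_child("a1", AttentionFCUnit(dim, dim, rng))
        self.a2 = self.add_child("a2", AttentionFCUnit(dim, dim, rng))
        self.f = self.add_child("f", FCUnit(dim, dim, rng))

    def __call__(self, x: Tensor) -> Tensor:
        return self.f(self.a2(self.a1(x))) + x


class TinyCNN(_Module):
    """Patchify conv + 3 strided conv blocks, global average pooled.

    The stride-4 entry convolution sees the raw discrete grayscale levels
    (no pre-pooling, which would blur the level alphabet the encoder
    relies on).
    """

    def __init__(self, embed_dim: int, rng: np.random.Generator, wide: bool = False):
        super().__init__()
        c = (32, 32, 64) if wide else (16, 16, 32)
        self.c0 = self.add_child("c0", Conv(3, c[0], 4, stride=4, padding=0, rng=rng))
        self.c1 = self.add_child("c1", Conv(c[0], c[1], 3, stride=2, padding=1, rng=rng))
        self.c2 = self.add_child("c2", Conv(c[1], c[2], 3, stride=2, padding=1, rng=rng))
        self.c3 = self.add_child("c3", Conv(c[2], c[2], 3, stride=2, padding=1, rng=rng))
        # rows (reads) are pooled out; the column axis is kept, because the
        # candidate site sits at a known x-position of the canvas while
        # bystander signatures from neighboring loci appear off-center
        self.proj = self.add_child("proj", Linear(c[2] * 7, embed_dim, rng))
        self.embed_dim = embed_dim

    def __call__(self, x: Tensor) -> Tensor:
        n = x.data.shape[0]
        h = self.c0(x).relu()           # 224 -> 56
        h = self.c1(h).relu()           # 56 -> 28
        h = self.c2(h).relu()           # 28 -> 14
        h = self.c3(h).relu()           # 14 -> 7
        profile = h.mean(axis=2)        # (N, C, 7): column profile
        return self.proj(profile.reshape(n, -1))


class SVClassifier(_Module):
    """Backbone -> attention residual module -> 3-class softmax."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.rng_seed)
        self.backbone = self.add_child(
            "backbone", TinyCNN(cfg.embed_dim, rng, wide=cfg.backbone == "tiny_cnn_wide")
        )
        self.head = self.add_child("head", AttentionResidualModule(cfg.embed_dim, rng))
        self.out = self.add_child("out", Linear(cfg.embed_dim, cfg.n_classes, rng))

    def logits(self, x: Tensor) -> Tensor:
        if self.cfg.mixed_precision or getattr(self, "mixed_precision", False):
            x = Tensor(x.data.astype(np.float16).astype(np.float32), requires_grad=False)
        return self.out(self.head(self.backbone(x)))

    def forward_probs(self, batch: np.ndarray) -> np.ndarray:
        """Inference: normalized (N,3,224,224) batch -> (N,3) probabilities."""
        if batch.ndim != 4 or batch.shape[1] != 3:
            raise ValueError(f"expected (N,3,H,W) normalized batch, got {batch.shape}")
        return softmax(self.logits(Tensor(batch)).data, axis=1)


def classify(batch: np.ndarray, model: SVClassifier) -> list[ClassProbabilities]:
    probs = model.forward_probs(batch)
    return [ClassProbabilities(*map(float, row)) for row in probs]


# ---------------------------------------------------------------------------
# checkpoints: single .npz with weights + JSON metadata, self-describing so
# the filtering stage can reproduce the exact encoding used in training.

def save_checkpoint(path: str | os.PathLike, model: SVClassifier,
                    grayscale_map: GrayscaleMap | None = None,
                    extension: int | None = None,
                    extra: dict | None = None) -> None:
    meta = {
        "model_config": vars(model.cfg) if not hasattr(model.cfg, "__dataclass_fields__")
        else {f: getattr(model.cfg, f) for f in model.cfg.__dataclass_fields__},
        "class_order": list(CLASS_ORDER),
        "grayscale_map": (grayscale_map or GrayscaleMap()).as_dict(),
        "extension": extension,
        "extra": extra or {},
    }
    arrays = {f"param:{k}": v.data for k, v in model.parameters().items()}
    np.savez(os.fspath(path), meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | os.PathLike) -> tuple[SVClassifier, dict]:
    with np.load(os.fspath(path)) as npz:
        meta = json.loads(bytes(npz["meta"]).decode())
        model = SVClassifier(ModelConfig(**meta["model_config"]))
        params = model.parameters()
        for key in npz.files:
            if key.startswith("param:"):
                name = key[len("param:"):]
                if name not in params:
                    raise KeyError(f"checkpoint parameter {name!r} not in model")
                params[name].data = npz[key].astype(np.float32)
    return model, meta


def load_backbone_weights(model: SVClassifier, checkpoint_path: str | os.PathLike) -> None:
    """Copy backbone.* weights from a (pre-training) checkpoint into ``model``."""
    with np.load(os.fspath(checkpoint_path)) as npz:
        params = model.parameters()
        for key in npz.files:
            if key.startswith("param:backbone."):
                name = key[len("param:"):]
                params[name].data = npz[key].astype(np.float32)


__all__ = [
    "CLASS_ORDER", "CLASS_INDEX", "ModelConfig", "ClassProbabilities",
    "predict_label", "Linear", "Conv", "AttentionFCUnit", "FCUnit",
    "AttentionResidualModule", "TinyCNN", "SVClassifier", "classify",
    "save_checkpoint", "load_checkpoint", "load_backbone_weights",
]
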