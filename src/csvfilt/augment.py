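"""Pre-processing for transfer learning: RGB conversion, color jitter, normalization.

The encoded site images are single-channel; convolutional backbones (and
any natural-image pre-trained weights) expect three channels, so the
grayscale image is replicated into RGB.  During training, random color
jitter increases data diversity; at filtering time the pipeline is a pure
deterministic function.  Values are scaled to [0, 1] and standardized per
channel before entering the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import CANVAS, EncodedImage

# channel statistics of the natural-image corpora the standard pre-trained
# backbones were fitted on; kept as the default so checkpoints are portable
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)

# Rec.601 luma weights, used for the saturation/contrast reference
_LUMA = np.array([0.299, 0.587, 0.114], dtype=np.float64)


@dataclass(frozen=True)
class AugmentConfig:
    jitter_brightness: float = 0.2
    jitter_contrast: float = 0.2
    jitter_saturation: float = 0.2
    jitter_hue: float = 0.05
    norm_mean: tuple[float, float, float] = IMAGENET_MEAN
    norm_std: tuple[float, float, float] = IMAGENET_STD
    train_mode: bool = False

    def __post_init__(self):
        for name in ("jitter_brightness", "jitter_contrast", "jitter_saturation", "jitter_hue"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(s <= 0 for s in self.norm_std):
            raise ValueError("norm_std must be positive per channel")


def to_rgb(img: EncodedImage | np.ndarray) -> np.ndarray:
    """Replicate a 224x224 grayscale image into 3 identical channels (float32, [0,255])."""
    pixels = img.pixels if isinstance(img, EncodedImage) else np.asarray(img)
    if pixels.shape != (CANVAS, CANVAS):
        raise ValueError(f"expected {CANVAS}x{CANVAS} grayscale, got {pixels.shape}")
    return np.repeat(pixels[None, :, :].astype(np.float32), 3, axis=0)


def _hue_shift(arr: np.ndarray, shift: float) -> np.ndarray:
    # identical channels are achromatic: hue rotation is then an exact no-op
    if np.array_equal(arr[0], arr[1]) and np.array_equal(arr[1], arr[2]):
        return arr
    from skimage.color import hsv2rgb, rgb2hsv

    hsv = rgb2hsv(np.moveaxis(arr / 255.0, 0, -1))
    hsv[..., 0] = (hsv[..., 0] + shift) % 1.0
    return np.moveaxis(hsv2rgb(hsv), -1, 0).astype(np.float32) * 255.0


def jitter(img: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Randomly perturb brightness, contrast, saturation and hue.

    Identity when ``train_mode`` is off or all jitter ranges are zero;
    deterministic given the generator state.  Output clamped to [0, 255].
    """
    if img.shape != (3, CANVAS, CANVAS):
        raise ValueError(f"expected 3x{CANVAS}x{CANVAS}, got {img.shape}")
    if not cfg.train_mode:
        return img
    out = img.astype(np.float32)
    if cfg.jitter_brightness > 0:
        f = rng.uniform(max(0.0, 1 - cfg.jitter_brightness), 1 + cfg.jitter_brightness)
        out = out * f
    if cfg.jitter_contrast > 0:
        f = rng.uniform(max(0.0, 1 - cfg.jitter_contrast), 1 + cfg.jitter_contrast)
        mean = float((_LUMA @ out.reshape(3, -1)).mean())
        out = mean + (out - mean) * f
    if cfg.jitter_saturation > 0:
        f = rng.uniform(max(0.0, 1 - cfg.jitter_saturation), 1 + cfg.jitter_saturation)
        luma = np.tensordot(_LUMA, out, axes=(0, 0))[None]
        out = luma + (out - luma) * f
    if cfg.jitter_hue > 0:
        shift = rng.uniform(-cfg.jitter_hue, cfg.jitter_hue)
        out = _hue_shift(out, shift)
    return np.clip(out, 0.0, 255.0).astype(np.float32)


def normalize(img: np.ndarray, cfg: AugmentConfig) -> np.ndarray:
    """Scale to [0, 1] then standardize each channel: (x - mean) / std."""
    if img.shape != (3, CANVAS, CANVAS):
        raise ValueError(f"expected 3x{CANVAS}x{CANVAS}, got {img.shape}")
    mean = np.asarray(cfg.norm_mean, dtype=np.float32)[:, None, None]
    std = np.asarray(cfg.norm_std, dtype=np.float32)[:, None, None]
    return (img.astype(np.float32) / 255.0 - mean) / std


def denormalize(img: np.ndarray, cfg: AugmentConfig) -> np.ndarray:
    """Inverse of :func:`normalize` (back to the [0, 255] scale)."""
    mean = np.asarray(cfg.norm_mean, dtype=np.float32)[:, None, None]
    std = np.asarray(cfg.norm_std, dtype=np.float32)[:, None, None]
    return (img * std + mean) * 255.0


def prepare(img: EncodedImage | np.ndarray, cfg: AugmentConfig,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """Full pipeline: to_rgb -> (jitter if training) -> normalize."""
    rgb = to_rgb(img)
    if cfg.train_mode:
        if rng is None:
            raise ValueError("training-mode augmentation needs an rng")
        rgb = jitter(rgb, cfg, rng)
    return normalize(rgb, cfg)


__all__ = [
    "AugmentConfig", "IMAGENET_MEAN", "IMAGENET_STD",
    "to_rgb", "jitter", "normalize", "denormalize", "prepare",
]
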