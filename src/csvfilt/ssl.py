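"""Self-supervised pre-training with variance-invariance-covariance regularization.

Two augmented views of each unlabeled site image are embedded by the
backbone plus a small expander projector; the loss combines
  - invariance: mean squared distance between paired view embeddings,
  - variance: a hinge keeping each embedding dimension's std above gamma,
  - covariance: the off-diagonal mass of each branch's covariance matrix,
which together prevent representational collapse without labels.  After
pre-training the projector is discarded and the backbone weights seed the
supervised fine-tuning stage.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentConfig, jitter, normalize, to_rgb
from .autodiff import Adam, Tensor
from .encoder import EncodedImage
from .model import GrayscaleMap, Linear, SVClassifier, _Module, save_checkpoint


@dataclass(frozen=True)
class VICRegConfig:
    sim_coeff: float = 25.0   # invariance weight
    std_coeff: float = 25.0   # variance weight
    cov_coeff: float = 1.0    # covariance weight
    gamma: float = 1.0        # variance hinge threshold
    epsilon: float = 1e-4     # numerical floor inside the std

    def __post_init__(self):
        if min(self.sim_coeff, self.std_coeff, self.cov_coeff) < 0:
            raise ValueError("loss coefficients must be non-negative")
        if self.gamma <= 0 or self.epsilon <= 0:
            raise ValueError("gamma and epsilon must be positive")


def _variance_term(z: Tensor, cfg: VICRegConfig) -> Tensor:
    std = (_center(z)[1] + cfg.epsilon).sqrt()
    return (Tensor(np.asarray(cfg.gamma, dtype=z.data.dtype)) - std).relu().mean()


def _center(z: Tensor) -> tuple[Tensor, Tensor]:
    n = z.data.shape[0]
    centered = z - z.mean(axis=0, keepdims=True)
    var = centered.pow(2.0).sum(axis=0) * (1.0 / (n - 1))
    return centered, var


def _covariance_term(z: Tensor) -> Tensor:
    n, d = z.data.shape
    centered, _ = _center(z)
    cov = centered.transpose(1, 0) @ centered * (1.0 / (n - 1))
    off_mask = (1.0 - np.eye(d)).astype(z.data.dtype)
    return (cov.pow(2.0) * off_mask).sum() * (1.0 / d)


def vicreg_loss(z_a: Tensor | np.ndarray, z_b: Tensor | np.ndarray,
                cfg: VICRegConfig | None = None) -> dict[str, Tensor]:
    """Weighted VICReg objective over two batches of paired embeddings.

    Returns the total and the three unweighted terms.  Variance is the
    average of the two branch hinges; covariance is summed over branches.
    """
    cfg = cfg or VICRegConfig()
    z_a = z_a if isinstance(z_a, Tensor) else Tensor(z_a)
    z_b = z_b if isinstance(z_b, Tensor) else Tensor(z_b)
    if z_a.data.shape != z_b.data.shape:
        raise ValueError("view embeddings must have the same shape")
    if z_a.data.shape[0] < 2:
        raise ValueError("batch size must be >= 2 (variance is undefined otherwise)")
    invariance = (z_a - z_b).pow(2.0).mean()
    variance = (_variance_term(z_a, cfg) + _variance_term(z_b, cfg)) * 0.5
    covariance = _covariance_term(z_a) + _covariance_term(z_b)
    total = cfg.sim_coeff * invariance + cfg.std_coeff * variance + cfg.cov_coeff * covariance
    return {"total": total, "invariance": invariance,
            "variance": variance, "covariance": covariance}


class Projector(_Module):
    """2-layer expander MLP on top of the backbone embedding; discarded after pre-training."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.l1 = self.add_child("l1", Linear(d_in, d_hidden, rng))
        self.l2 = self.add_child("l2", Linear(d_hidden, d_out, rng))

    def __call__(self, x: Tensor) -> Tensor:
        return self.l2(self.l1(x).relu())


def make_views(img: EncodedImage | np.ndarray, cfg: AugmentConfig,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two independent jitter+normalize draws of the same image."""
    rgb = to_rgb(img)
    return (normalize(jitter(rgb, cfg, rng), cfg),
            normalize(jitter(rgb, cfg, rng), cfg))


def encode_read_resample_pairs(bam, sites, enc_cfg=None, rng_seed: int = 0) -> np.ndarray:
    """Encode two images per site from disjoint random halves of its reads.

    Color jitter alone yields weak view pairs for level-coded images (the
    two views differ only by an affine intensity map).  Splitting the
    reads of a locus into two halves instead produces views that share
    the locus signature but differ in read sampling, so the invariance
    term pulls together what genuinely identifies the site.  Returns a
    (n_sites, 2, 224, 224) uint8 array; sites with < 2 reads are skipped.
    """
    import pysam

    from .encoder import EncoderConfig, encode_raw_image, extend_region, resize_to_canvas
    from .formats_io import fetch_alignments

    enc_cfg = enc_cfg or EncoderConfig()
    rng = np.random.default_rng(rng_seed)
    own = not isinstance(bam, pysam.AlignmentFile)
    af = pysam.AlignmentFile(os.fspath(bam)) if own else bam
    pairs = []
    try:
        for site in sites:
            chrom_length = af.get_reference_length(site.chrom)
            region = extend_region(site, enc_cfg.extension, chrom_length)
            reads = fetch_alignments(af, region, min_mapq=enc_cfg.min_mapq,
                                     primary_only=enc_cfg.primary_only)
            if len(reads) < 2:
                continue
            order = rng.permutation(len(reads))
            half = len(reads) // 2
            views = []
            for sel in (order[:half], order[half:]):
                subset = [reads[i] for i in sorted(sel)]
                views.append(resize_to_canvas(encode_raw_image(subset, enc_cfg), enc_cfg).pixels)
            pairs.append(np.stack(views))
    finally:
        if own:
            af.close()
    if not pairs:
        raise RuntimeError("no site had enough reads to build view pairs")
    return np.stack(pairs)


def pretrain(
    images: list[EncodedImage] | np.ndarray,
    model: SVClassifier,
    out_path: str | os.PathLike,
    vicreg_cfg: VICRegConfig | None = None,
    aug_cfg: AugmentConfig | None = None,
    epochs: int = 5,
    batch_size: int = 16,
    learning_rate: float = 1e-3,
    projector_dim: int = 64,
    rng_seed: int = 0,
    grayscale_map: GrayscaleMap | None = None,
    extension: int | None = None,
) -> list[dict[str, float]]:
    """Optimize the backbone on the VICReg objective over paired views.

    ``images`` may be single images (each pair is then two jitter draws
    of the same image, :func:`make_views`) or pre-built view pairs of
    shape (n, 2, H, W) from :func:`encode_read_resample_pairs`, which
    still receive independent jitter.  Writes a checkpoint (without the
    projector) to ``out_path`` and returns the per-epoch loss history.
    """
    if len(images) == 0:
        raise ValueError("pre-training needs a non-empty image set")
    vicreg_cfg = vicreg_cfg or VICRegConfig()
    aug_cfg = aug_cfg or AugmentConfig(train_mode=True)
    if not aug_cfg.train_mode:
        aug_cfg = AugmentConfig(**{**_cfg_dict(aug_cfg), "train_mode": True})
    rng = np.random.default_rng(rng_seed)
    projector = Projector(model.cfg.embed_dim, projector_dim, projector_dim, rng)
    params = {**model.parameters(prefix="model."), **projector.parameters(prefix="proj.")}
    # only the backbone (and projector) learn here; the head is supervised later
    frozen = {k for k in params if k.startswith(("model.head.", "model.out."))}
    opt = Adam(params, lr=learning_rate, frozen=frozen)

    raw = [img.pixels if isinstance(img, EncodedImage) else np.asarray(img) for img in images]
    paired = raw[0].ndim == 3  # (2, H, W) per item: pre-built view pairs

    def _views(item):
        if not paired:
            return make_views(item, aug_cfg, rng)
        return (normalize(jitter(to_rgb(item[0]), aug_cfg, rng), aug_cfg),
                normalize(jitter(to_rgb(item[1]), aug_cfg, rng), aug_cfg))

    history: list[dict[str, float]] = []
    for epoch in range(epochs):
        order = rng.permutation(len(raw))
        sums = {"total": 0.0, "invariance": 0.0, "variance": 0.0, "covariance": 0.0}
        n_batches = 0
        for start in range(0, len(order), batch_size):
            idx = order[start:start + batch_size]
            if len(idx) < 2:
                continue
            views = [_views(raw[i]) for i in idx]
            batch_a = np.stack([v[0] for v in views])
            batch_b = np.stack([v[1] for v in views])
            z_a = projector(model.backbone(Tensor(batch_a)))
            z_b = projector(model.backbone(Tensor(batch_b)))
            losses = vicreg_loss(z_a, z_b, vicreg_cfg)
            opt.zero_grad()
            losses["total"].backward()
            opt.step()
            for key in sums:
                sums[key] += float(losses[key].data)
            n_batches += 1
        history.append({"epoch": epoch, **{k: v / max(n_batches, 1) for k, v in sums.items()}})
    save_checkpoint(out_path, model, grayscale_map=grayscale_map, extension=extension,
                    extra={"stage": "ssl_pretrain", "epochs": epochs})
    return history


def _cfg_dict(cfg) -> dict:
    return {f: getattr(cfg, f) for f in cfg.__dataclass_fields__}


__all__ = ["VICRegConfig", "vicreg_loss", "make_views", "Projector", "pretrain"]
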