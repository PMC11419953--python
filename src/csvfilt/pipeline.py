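"""End-to-end orchestration: sites -> images -> training -> filtering -> scoring.

Thin glue over the other modules, used by the command-line interface and
by the benchmark scripts; no science of its own lives here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .augment import AugmentConfig
from .encoder import EncodedImage, EncoderConfig, encode_site
from .filtering import MatchConfig, filter_vcf, match_calls, precision_recall
from .formats_io import SVRecord, read_sv_vcf
from .model import ModelConfig, SVClassifier, save_checkpoint
from .negatives import NegativeSamplingConfig, estimate_lambda, sample_negative_sites
from .simulate import SimConfig, simulate_dataset
from .training import TrainConfig, evaluate, finetune, split_dataset


def benchmark_sim_config(seed: int = 17) -> SimConfig:
    """Desk-benchmark preset: ~600 site images (300 SVs + 300 negatives).

    The SV count is scaled up from the simulator default (60+60 on 2 Mb)
    with the chromosome scaled in proportion, so the SV density — and with
    it the difficulty of the negative class — stays at the default level.
    """
    return SimConfig(chrom_length=5_000_000, n_ins=150, n_del=150, rng_seed=seed)


def ssl_sim_config(seed: int = 17) -> SimConfig:
    """Preset for the self-supervised comparison: 500 site images."""
    return SimConfig(chrom_length=4_200_000, n_ins=125, n_del=125, rng_seed=seed)


def build_site_list(truth: list[SVRecord], chrom_lengths: dict[str, int],
                    seed: int = 0, n_negatives: int | None = None) -> list[SVRecord]:
    """Truth SVs plus generated negatives (default: one negative per true SV)."""
    model = estimate_lambda([sv.svlen for sv in truth])
    cfg = NegativeSamplingConfig(
        n_target=len(truth) if n_negatives is None else n_negatives,
        rng_seed=seed,
    )
    return list(truth) + sample_negative_sites(truth, chrom_lengths, model, cfg)


def encode_sites(bam_path, sites: list[SVRecord],
                 enc_cfg: EncoderConfig | None = None) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Encode every site with coverage; returns (images, labels, site_ids)."""
    enc_cfg = enc_cfg or EncoderConfig()
    images, labels, ids = [], [], []
    with pysam.AlignmentFile(os.fspath(bam_path)) as af:
        for site in sites:
            img = encode_site(af, site, enc_cfg)
            if img is None:
                continue
            images.append(img.pixels)
            labels.append(site.svtype)
            ids.append(site.id)
    if not images:
        raise RuntimeError("no site had read coverage; nothing to encode")
    return np.stack(images), np.asarray(labels), ids


@dataclass
class BenchmarkResult:
    """Everything the desk-scale benchmark measures on one simulated genome."""

    test_macro_f1: float
    test_accuracy: float
    precision_before: float
    recall_before: float
    f1_before: float
    precision_after: float
    recall_after: float
    f1_after: float
    n_images: int
    n_dropped: int
    history: list = field(default_factory=list)


def run_benchmark(
    work_dir: str | os.PathLike,
    sim_cfg: SimConfig | None = None,
    train_cfg: TrainConfig | None = None,
    enc_cfg: EncoderConfig | None = None,
    model_cfg: ModelConfig | None = None,
    seed: int = 17,
    policy: str = "drop_neg",
) -> BenchmarkResult:
    """Simulate, encode, train a tiny model, filter the caller VCF and score it.

    The measurement mirrors how an SV-filtering tool is judged on real
    data: precision/recall of the caller VCF against the truth set before
    and after filtering, plus the classifier's own held-out macro-F1.
    """
    work = Path(work_dir)
    sim_cfg = sim_cfg or SimConfig(rng_seed=seed)
    enc_cfg = enc_cfg or EncoderConfig()
    train_cfg = train_cfg or TrainConfig(rng_seed=seed)

    data = simulate_dataset(work / "sim", sim_cfg)
    chrom_lengths = {sim_cfg.chrom: sim_cfg.chrom_length}
    sites = build_site_list(data["truth"], chrom_lengths, seed=seed)
    images, labels, _ = encode_sites(data["bam"], sites, enc_cfg)

    tr, va, te = split_dataset(labels, train_cfg.split_fractions, seed=seed)
    model = SVClassifier(model_cfg or ModelConfig(rng_seed=seed))
    model, history = finetune(model, images[tr], labels[tr], images[va], labels[va],
                              train_cfg)
    test_report = evaluate(model, images[te], labels[te])

    ckpt = work / "model.npz"
    save_checkpoint(ckpt, model, grayscale_map=enc_cfg.grayscale_map,
                    extension=enc_cfg.extension)

    truth = data["truth"]
    calls_before = read_sv_vcf(data["caller_vcf"], allowed_types={"INS", "DEL"})
    p0, r0, f0 = precision_recall(*match_calls(calls_before, truth)[:3])

    filtered_vcf = work / "calls.filtered.vcf"
    decisions = filter_vcf(ckpt, data["bam"], data["caller_vcf"], filtered_vcf, policy=policy)
    calls_after = read_sv_vcf(filtered_vcf, allowed_types={"INS", "DEL"})
    p1, r1, f1 = precision_recall(*match_calls(calls_after, truth)[:3])

    return BenchmarkResult(
        test_macro_f1=test_report.macro_f1,
        test_accuracy=test_report.accuracy,
        precision_before=p0, recall_before=r0, f1_before=f0,
        precision_after=p1, recall_after=r1, f1_after=f1,
        n_images=len(images),
        n_dropped=sum(not d.keep for d in decisions),
        history=history,
    )


def run_ssl_comparison(
    work_dir: str | os.PathLike,
    sim_cfg: SimConfig | None = None,
    seed: int = 17,
    pretrain_epochs: int = 5,
    finetune_epochs: int = 10,
    label_fraction: float = 0.25,
) -> tuple[float, float]:
    """Self-supervised pre-training vs from-scratch, matched head training.

    Pre-trains the backbone with the variance-invariance-covariance
    objective on unlabeled read-resampled view pairs of every site, then
    fine-tunes with the backbone frozen on a label-scarce subset of the
    training split — the regime self-supervised learning is meant for:
    representations come from unlabeled data, labels are the bottleneck,
    and freezing isolates what pre-training contributed.  The from-scratch
    arm trains its (randomly initialized, equally frozen) backbone's head
    on the identical subset with the identical schedule and seed.  Both
    arms are scored on an independently simulated test genome.  Returns
    (pretrained macro-F1, scratch macro-F1).
    """
    from .model import load_backbone_weights
    from .ssl import encode_read_resample_pairs, pretrain

    work = Path(work_dir)
    sim_cfg = sim_cfg or SimConfig(rng_seed=seed)
    data = simulate_dataset(work / "sim", sim_cfg)
    sites = build_site_list(data["truth"], {sim_cfg.chrom: sim_cfg.chrom_length}, seed=seed)
    images, labels, _ = encode_sites(data["bam"], sites)
    tr, va, _ = split_dataset(labels, seed=seed)
    if label_fraction < 1.0:
        sub_rng = np.random.default_rng(seed)
        keep = np.sort(sub_rng.permutation(len(tr))[:max(3, int(round(label_fraction * len(tr))))])
        tr = tr[keep]

    # held-out genome: same study conditions, independent seed
    ext_cfg = SimConfig(rng_seed=seed + 1000)
    ext = simulate_dataset(work / "sim_test", ext_cfg)
    ext_sites = build_site_list(ext["truth"], {ext_cfg.chrom: ext_cfg.chrom_length},
                                seed=seed + 1000)
    ext_images, ext_labels, _ = encode_sites(ext["bam"], ext_sites)

    ssl_ckpt = work / "ssl.npz"
    model_pre = SVClassifier(ModelConfig(rng_seed=seed))
    pairs = encode_read_resample_pairs(data["bam"], sites, rng_seed=seed)
    pretrain(list(pairs), model_pre, ssl_ckpt, epochs=pretrain_epochs, rng_seed=seed)
    load_backbone_weights(model_pre, ssl_ckpt)

    train_cfg = TrainConfig(epochs=finetune_epochs, rng_seed=seed,
                            freeze_layers=("backbone.",))
    results = []
    for model in (model_pre, SVClassifier(ModelConfig(rng_seed=seed))):
        model, _ = finetune(model, images[tr], labels[tr], images[va], labels[va], train_cfg)
        results.append(evaluate(model, ext_images, ext_labels).macro_f1)
    return results[0], results[1]


__all__ = ["benchmark_sim_config", "ssl_sim_config", "build_site_list",
           "encode_sites", "BenchmarkResult", "run_benchmark", "run_ssl_comparison"]
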