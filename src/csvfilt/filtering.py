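"""Apply a trained classifier to a caller's VCF and score against a truth set.

Each INS/DEL call is re-encoded from the BAM exactly as during training
(the checkpoint carries the grayscale map and window extension), classified,
and kept or dropped by policy:

- ``drop_neg`` (default): drop only calls the model predicts to be
  negative (no-SV) sites — the false positives.
- ``strict_match``: additionally drop calls whose predicted class differs
  from the reported SVTYPE.

Zero-coverage calls are conservatively kept.  A small built-in matcher
(breakpoint distance + size similarity, the same thresholds commonly used
for SV benchmarking) scores callsets against a truth set.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pysam

from .augment import AugmentConfig, prepare
from .encoder import EncoderConfig, GrayscaleMap, encode_site
from .formats_io import SVRecord, read_sv_vcf, write_filtered_vcf
from .model import ClassProbabilities, SVClassifier, load_checkpoint, predict_label

logger = logging.getLogger(__name__)

POLICIES = ("drop_neg", "strict_match")


@dataclass(frozen=True)
class FilterDecision:
    record_id: str
    predicted: str
    probabilities: ClassProbabilities
    keep: bool
    reason: str  # predicted_negative | type_mismatch | zero_coverage_kept | passed

    def __post_init__(self):
        if not self.keep and self.reason not in ("predicted_negative", "type_mismatch"):
            raise ValueError(f"dropped record must cite a drop reason, got {self.reason!r}")


@dataclass(frozen=True)
class MatchConfig:
    ref_dist: int = 500      # max breakpoint distance (bp)
    size_sim: float = 0.5    # min(len)/max(len) threshold
    seq_sim: float = 0.0     # sequence similarity is not used by the matcher

    def __post_init__(self):
        if self.ref_dist < 0:
            raise ValueError("ref_dist must be >= 0")
        if not (0 <= self.size_sim <= 1):
            raise ValueError("size_sim must be in [0, 1]")


def filter_calls(
    checkpoint: str | os.PathLike | tuple[SVClassifier, dict],
    bam: str | os.PathLike,
    caller_vcf: str | os.PathLike,
    policy: str = "drop_neg",
    aug_cfg: AugmentConfig | None = None,
    batch_size: int = 32,
) -> list[FilterDecision]:
    """Classify every INS/DEL record of ``caller_vcf`` and decide keep/drop."""
    if policy not in POLICIES:
        raise ValueError(f"policy must be one of {POLICIES}")
    model, meta = load_checkpoint(checkpoint) if not isinstance(checkpoint, tuple) else checkpoint
    enc_cfg = EncoderConfig(
        extension=meta.get("extension") or EncoderConfig().extension,
        grayscale_map=GrayscaleMap(**{f"level_{k}": v
                                      for k, v in meta["grayscale_map"].items()}),
    )
    aug_cfg = aug_cfg or AugmentConfig(train_mode=False)
    records = read_sv_vcf(caller_vcf, allowed_types={"INS", "DEL"})
    decisions: list[FilterDecision] = []
    uniform = ClassProbabilities(1 / 3, 1 / 3, 1 / 3)
    with pysam.AlignmentFile(os.fspath(bam)) as af:
        contigs = set(af.references)
        pending: list[tuple[SVRecord, np.ndarray]] = []

        def flush():
            if not pending:
                return
            batch = np.stack([prepare(img, aug_cfg) for _, img in pending])
            probs = model.forward_probs(batch)
            for (rec, _), p in zip(pending, probs):
                cp = ClassProbabilities(*map(float, p))
                predicted = predict_label(cp)
                if predicted == "NEG":
                    keep, reason = False, "predicted_negative"
                elif policy == "strict_match" and predicted != rec.svtype:
                    keep, reason = False, "type_mismatch"
                else:
                    keep, reason = True, "passed"
                decisions.append(FilterDecision(rec.id, predicted, cp, keep, reason))
            pending.clear()

        for rec in records:
            if rec.chrom not in contigs:
                logger.warning("contig %s absent from BAM; keeping record %s", rec.chrom, rec.id)
                decisions.append(FilterDecision(rec.id, rec.svtype, uniform, True, "zero_coverage_kept"))
                continue
            img = encode_site(af, rec, enc_cfg)
            if img is None:
                decisions.append(FilterDecision(rec.id, rec.svtype, uniform, True, "zero_coverage_kept"))
                continue
            pending.append((rec, img.pixels))
            if len(pending) >= batch_size:
                flush()
        flush()
    # restore input order (zero-coverage decisions were appended out of batch order)
    order = {rec.id: i for i, rec in enumerate(records)}
    decisions.sort(key=lambda d: order[d.record_id])
    return decisions


def filter_vcf(checkpoint, bam, caller_vcf, out_path, policy: str = "drop_neg") -> list[FilterDecision]:
    """filter_calls + write the filtered VCF; returns the decisions."""
    decisions = filter_calls(checkpoint, bam, caller_vcf, policy=policy)
    write_filtered_vcf(caller_vcf, decisions, out_path,
                       provenance=f"csvfilt-0.1.0,policy={policy}")
    return decisions


def match_calls(
    calls: list[SVRecord],
    truth: list[SVRecord],
    cfg: MatchConfig | None = None,
) -> tuple[int, int, int, list[tuple[SVRecord, SVRecord]]]:
    """Greedy 1-1 matching of calls against truth records.

    A call matches a same-SVTYPE truth record when the breakpoint distance
    is at most ``ref_dist`` and min(len)/max(len) >= ``size_sim``; each
    truth record is used once, calls processed in position order, ties to
    the nearest truth record.  Returns (TP, FP, FN, matched pairs).
    """
    cfg = cfg or MatchConfig()
    used: set[int] = set()
    pairs: list[tuple[SVRecord, SVRecord]] = []
    tp = fp = 0
    for call in sorted(calls, key=lambda r: (r.chrom, r.pos, r.id)):
        best, best_dist = None, None
        for j, t in enumerate(truth):
            if j in used or t.chrom != call.chrom or t.svtype != call.svtype:
                continue
            dist = abs(call.pos - t.pos)
            if dist > cfg.ref_dist:
                continue
            ratio = min(call.svlen, t.svlen) / max(call.svlen, t.svlen)
            if ratio < cfg.size_sim:
                continue
            if best_dist is None or dist < best_dist:
                best, best_dist = j, dist
        if best is None:
            fp += 1
        else:
            used.add(best)
            pairs.append((call, truth[best]))
            tp += 1
    fn = len(truth) - len(used)
    return tp, fp, fn, pairs


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1 from match counts (0 when undefined)."""
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


__all__ = [
    "FilterDecision", "MatchConfig", "POLICIES",
    "filter_calls", "filter_vcf", "match_calls", "precision_recall",
]
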