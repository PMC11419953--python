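"""Negative (no-SV) site generation.

The classifier needs a null class: genomic intervals that carry no
structural variant.  Their lengths are drawn from a Poisson law whose
rate is the harmonic mean of the sample mean and sample variance of the
true SV lengths, so that negatives are length-matched to the positives.
Candidate placements that overlap true SVs by more than a configurable
fraction of their own length are rejected and redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .formats_io import SVRecord


@dataclass(frozen=True)
class PoissonNegativeModel:
    """Poisson rate for negative-site lengths, fitted from true SV lengths."""

    m: float            # sample mean of SV lengths
    v: float            # unbiased sample variance of SV lengths
    lambda_neg: float   # harmonic mean of (m, v); equals m when v == 0

    def __post_init__(self):
        if self.m <= 0:
            raise ValueError("mean SV length must be positive")
        if self.v < 0:
            raise ValueError("variance cannot be negative")
        if self.lambda_neg <= 0:
            raise ValueError("lambda_neg must be positive")


@dataclass(frozen=True)
class NegativeSamplingConfig:
    n_target: int
    max_overlap_fraction: float = 0.5
    rng_seed: int = 0
    min_len: int = 50        # SV definition floor
    max_len: int = 100_000
    max_draw_factor: int = 50  # iteration cap = factor * n_target

    def __post_init__(self):
        if not (0 < self.max_overlap_fraction <= 1):
            raise ValueError("max_overlap_fraction must be in (0, 1]")
        if self.n_target < 0:
            raise ValueError("n_target must be >= 0")


def estimate_lambda(sv_lengths) -> PoissonNegativeModel:
    """Fit the negative-length Poisson rate from observed SV lengths.

    lambda_neg = 2*m*v / (m + v), the harmonic mean of the sample mean m
    and the unbiased sample variance v; degenerates to m when v = 0.
    """
    lengths = np.asarray(sv_lengths, dtype=float)
    if lengths.size < 2:
        raise ValueError("need at least 2 SV lengths to estimate lambda")
    m = float(lengths.mean())
    v = float(lengths.var(ddof=1))
    lam = m if v == 0 else 2.0 * m * v / (m + v)
    return PoissonNegativeModel(m=m, v=v, lambda_neg=lam)


def poisson_pmf(k, lam: float):
    """P(X = k) = exp(-lam) * lam**k / k!, evaluated in log space."""
    k_arr = np.asarray(k)
    if np.any(k_arr < 0):
        raise ValueError("k must be non-negative")
    if lam <= 0:
        raise ValueError("lam must be positive")
    out = stats.poisson.pmf(k_arr, lam)
    return float(out) if np.isscalar(k) or k_arr.ndim == 0 else out


def _overlap_with_svs(start: int, end: int, sv_starts: np.ndarray, sv_ends: np.ndarray) -> int:
    """Total overlap (bp) of [start, end) with a set of intervals."""
    if sv_starts.size == 0:
        return 0
    lo = np.maximum(sv_starts, start)
    hi = np.minimum(sv_ends, end)
    return int(np.clip(hi - lo, 0, None).sum())


def sample_negative_sites(
    svs: list[SVRecord],
    chrom_lengths: dict[str, int],
    model: PoissonNegativeModel,
    cfg: NegativeSamplingConfig,
) -> list[SVRecord]:
    """Draw ``cfg.n_target`` negative sites, rejecting heavy overlaps with true SVs.

    Lengths ~ Poisson(lambda_neg), clipped into [min_len, max_len]; the
    chromosome is chosen proportional to its length and the start uniform
    on it.  A candidate overlapping true SVs by more than
    ``max_overlap_fraction`` of its own length is redrawn.  Deterministic
    given ``cfg.rng_seed``.
    """
    for sv in svs:
        if sv.chrom not in chrom_lengths:
            raise KeyError(f"SV chromosome {sv.chrom!r} missing from chrom_lengths")
    rng = np.random.default_rng(cfg.rng_seed)
    chroms = sorted(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in chroms:
        cs = [sv for sv in svs if sv.chrom == c]
        by_chrom[c] = (
            np.array([sv.pos - 1 for sv in cs], dtype=np.int64),
            np.array([sv.end if sv.svtype != "INS" else sv.pos - 1 + sv.svlen for sv in cs],
                     dtype=np.int64),
        )

    out: list[SVRecord] = []
    draws = 0
    cap = max(1, cfg.max_draw_factor * max(cfg.n_target, 1))
    while len(out) < cfg.n_target:
        if draws >= cap:
            raise RuntimeError(
                f"negative sampling exceeded {cap} draws after accepting "
                f"{len(out)}/{cfg.n_target}; the genome is too crowded — "
                "reduce n_target or relax max_overlap_fraction"
            )
        draws += 1
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        clen = chrom_lengths[chrom]
        length = int(np.clip(rng.poisson(model.lambda_neg), cfg.min_len, cfg.max_len))
        start = int(rng.integers(0, max(clen - 1, 1)))
        end = min(start + length, clen)
        length = end - start
        if length < 1:
            continue
        sv_starts, sv_ends = by_chrom[chrom]
        overlap = _overlap_with_svs(start, end, sv_starts, sv_ends)
        if overlap > cfg.max_overlap_fraction * length:
            continue
        idx = len(out)
        out.append(
            SVRecord(id=f"NEG:{chrom}:{start + 1}:{idx}", chrom=chrom,
                     pos=start + 1, end=end, svtype="NEG", svlen=length,
                     source="generated")
        )
    return out


__all__ = [
    "PoissonNegativeModel", "NegativeSamplingConfig",
    "estimate_lambda", "poisson_pmf", "sample_negative_sites",
]
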