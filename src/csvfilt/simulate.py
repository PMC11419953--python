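"""Synthetic reference + reads + callsets with faithful CIGAR SV signatures.

Builds everything the rest of the package consumes, with no external
data: a random reference chromosome, a truth set of implanted insertions
and deletions, an aligned read set written directly as a sorted indexed
BAM (reads spanning a deletion carry a D run of the deletion length,
reads spanning an insertion carry an I run, and a configurable fraction
of breakpoint reads are soft-clipped instead — the canonical signatures a
long- or short-read aligner produces at SV loci), and a "caller" VCF made
of position/length-jittered truth calls contaminated with injected false
positives at variant-free locations.

The CIGAR strings are written directly by construction rather than via a
read aligner: the package under test is the encoder and classifier, not
an alignment pipeline.  Background noise is limited to sporadic 1-bp
indels; chimeric reads and mapping artifacts of real data are not
emulated.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pysam

from .formats_io import SVRecord, cigar_to_string

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    chrom: str = "chr1"
    chrom_length: int = 2_000_000
    n_ins: int = 60
    n_del: int = 60
    sv_len_lambda: float = 300.0     # Poisson rate for SV lengths (bp)
    coverage: float = 20.0           # mean depth
    read_length: int = 2000          # long-read mode; 150 for short-read mode
    clip_fraction: float = 0.3       # breakpoint reads soft-clipped instead of spanning
    fp_rate: float = 0.5             # injected false calls as a fraction of |truth|
    noise_mismatch_rate: float = 5e-4  # per-base 1-bp indel noise in background reads
    rng_seed: int = 17

    def __post_init__(self):
        if min(self.n_ins, self.n_del) < 0 or self.coverage < 0:
            raise ValueError("counts and coverage must be >= 0")
        for name in ("clip_fraction", "fp_rate"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.chrom_length <= 10 * self.read_length:
            raise ValueError("chrom_length must exceed 10 x read_length")

    @staticmethod
    def short_read(**overrides) -> "SimConfig":
        return SimConfig(**{"read_length": 150, **overrides})


def simulate_truth(cfg: SimConfig) -> tuple[np.ndarray, list[SVRecord]]:
    """Random reference plus non-overlapping implanted SV truth records.

    SV anchor points keep at least 2 x read_length spacing; lengths are
    max(50, Poisson(sv_len_lambda)).  Deterministic by seed.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    reference = _BASES[rng.integers(0, 4, size=cfg.chrom_length)]
    n = cfg.n_ins + cfg.n_del
    if n == 0:
        return reference, []
    gap = 2 * cfg.read_length
    lengths = np.maximum(50, rng.poisson(cfg.sv_len_lambda, size=n))
    # sorted-uniform placement with a guaranteed gap between consecutive sites
    budget = cfg.chrom_length - (n + 1) * gap - int(lengths.sum())
    if budget <= 0:
        raise ValueError(
            f"cannot place {n} SVs with {gap} bp spacing on a {cfg.chrom_length} bp "
            "chromosome; use a longer chromosome or fewer SVs"
        )
    slack = np.sort(rng.uniform(0, budget, size=n))
    types = np.array(["INS"] * cfg.n_ins + ["DEL"] * cfg.n_del)
    rng.shuffle(types)
    truth: list[SVRecord] = []
    cursor = 0.0
    for i in range(n):
        start0 = int(slack[i]) + gap * (i + 1) + int(cursor)
        svtype = str(types[i])
        svlen = int(lengths[i])
        pos = start0 + 1  # 1-based
        end = pos + svlen if svtype == "DEL" else pos
        truth.append(SVRecord(id=f"truth_{i:04d}", chrom=cfg.chrom, pos=pos, end=end,
                              svtype=svtype, svlen=svlen, source="truth"))
        if svtype == "DEL":
            cursor += svlen
    return reference, truth


def _noise_cigar(read_length: int, rate: float, rng: np.random.Generator) -> list[tuple[str, int]]:
    """Mostly-M CIGAR with sporadic 1-bp I/D noise splitting the match run."""
    k = int(rng.poisson(read_length * rate))
    if k == 0:
        return [("M", read_length)]
    cuts = np.sort(rng.integers(1, read_length, size=k))
    ops: list[tuple[str, int]] = []
    prev = 0
    for cut in cuts:
        if cut <= prev:
            continue
        ops.append(("M", int(cut - prev)))
        ops.append(("I" if rng.random() < 0.5 else "D", 1))
        prev = int(cut)
    ops.append(("M", read_length - prev))
    return [op for op in ops if op[1] > 0]


def _read_cigar(start: int, sv: SVRecord | None, cfg: SimConfig,
                rng: np.random.Generator, margin: int) -> list[tuple[str, int]]:
    """CIGAR of a read starting at ``start`` (0-based), honoring SV signatures."""
    rl = cfg.read_length
    if sv is not None:
        a = (sv.pos - 1) - start  # offset of the 0-based breakpoint into the read
        if margin <= a <= rl - margin:
            if rng.random() < cfg.clip_fraction:
                return [("M", a), ("S", rl - a)]
            if sv.svtype == "DEL":
                return [("M", a), ("D", sv.svlen), ("M", rl - a)]
            return [("M", a), ("I", sv.svlen), ("M", rl - a)]
    return _noise_cigar(rl, cfg.noise_mismatch_rate, rng)


def simulate_reads(reference: np.ndarray, truth: list[SVRecord], cfg: SimConfig,
                   bam_path: str | os.PathLike) -> int:
    """Write a coordinate-sorted, indexed BAM of simulated reads; returns read count."""
    rng = np.random.default_rng(cfg.rng_seed + 1)
    chrom_length = len(reference)
    n_reads = int(round(cfg.coverage * chrom_length / cfg.read_length))
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": cfg.chrom, "LN": chrom_length}]}
    bam_path = os.fspath(bam_path)
    starts = np.sort(rng.integers(0, max(chrom_length - cfg.read_length, 1), size=n_reads))
    margin = min(100, cfg.read_length // 4)
    anchors = np.array([sv.pos - 1 for sv in truth], dtype=np.int64)
    # SV breakpoints are spaced >= 2 x read_length apart, so each read can
    # cover at most one; locate it by binary search on the anchor list.
    nearest = np.searchsorted(anchors, starts) if len(truth) else None
    with pysam.AlignmentFile(bam_path, "wb", header=header) as out:
        for i, start in enumerate(starts):
            sv = None
            if nearest is not None:
                j = int(nearest[i])
                if j < len(truth) and anchors[j] - start <= cfg.read_length:
                    sv = truth[j]
            ops = _read_cigar(int(start), sv, cfg, rng, margin)
            qlen = sum(l for c, l in ops if c in "MIS=X")
            seg = pysam.AlignedSegment()
            seg.query_name = f"read_{i:06d}"
            seg.query_sequence = bytes(_BASES[rng.integers(0, 4, size=qlen)]).decode()
            seg.flag = 0
            seg.reference_id = 0
            seg.reference_start = int(start)
            seg.mapping_quality = 60
            seg.cigarstring = cigar_to_string(ops)
            out.write(seg)
    pysam.index(bam_path)
    return n_reads


def _vcf_header(cfg: SimConfig) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.contigs.add(cfg.chrom, length=cfg.chrom_length)
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("SVLEN", 1, "Integer", "Length of structural variant")
    return header  # htslib declares END itself when a record's stop is set


def write_sv_vcf(records: list[SVRecord], cfg: SimConfig, path: str | os.PathLike) -> None:
    """Write SV records as an uncompressed VCF (SVLEN negative for DEL, by convention)."""
    header = _vcf_header(cfg)
    with pysam.VariantFile(os.fspath(path), "w", header=header) as vf:
        for rec in sorted(records, key=lambda r: r.pos):
            out = vf.new_record(
                contig=cfg.chrom, start=rec.pos - 1,
                stop=rec.end if rec.svtype == "DEL" else rec.pos,
                alleles=("N", f"<{rec.svtype}>"), id=rec.id,
            )
            out.info["SVTYPE"] = rec.svtype
            out.info["SVLEN"] = -rec.svlen if rec.svtype == "DEL" else rec.svlen
            vf.write(out)


def make_caller_vcf(truth: list[SVRecord], cfg: SimConfig,
                    rng: np.random.Generator) -> list[SVRecord]:
    """Jittered truth calls plus injected false positives >= 1 kb from any truth SV."""
    calls: list[SVRecord] = []
    for i, t in enumerate(truth):
        pos = max(1, t.pos + int(rng.integers(-50, 51)))
        svlen = max(1, int(round(t.svlen * rng.uniform(0.9, 1.1))))
        end = pos + svlen if t.svtype == "DEL" else pos
        calls.append(SVRecord(id=f"call_{i:04d}", chrom=t.chrom, pos=pos, end=end,
                              svtype=t.svtype, svlen=svlen, source="caller"))
    n_fp = int(round(cfg.fp_rate * len(truth)))
    spans = [(t.pos - 1 - 1000, (t.end if t.svtype == "DEL" else t.pos) + 1000) for t in truth]
    placed = 0
    attempts = 0
    while placed < n_fp:
        attempts += 1
        if attempts > 1000 * max(n_fp, 1):
            raise RuntimeError("could not place false-positive calls 1 kb away from truth")
        start0 = int(rng.integers(1000, cfg.chrom_length - 1000))
        if any(lo <= start0 < hi for lo, hi in spans):
            continue
        svtype = "INS" if rng.random() < 0.5 else "DEL"
        svlen = max(50, int(rng.poisson(cfg.sv_len_lambda)))
        pos = start0 + 1
        end = pos + svlen if svtype == "DEL" else pos
        calls.append(SVRecord(id=f"fp_{placed:04d}", chrom=cfg.chrom, pos=pos, end=end,
                              svtype=svtype, svlen=svlen, source="caller"))
        placed += 1
    return calls


def simulate_dataset(out_dir: str | os.PathLike, cfg: SimConfig | None = None) -> dict:
    """Write reference FASTA(+fai), BAM(+bai), truth VCF and caller VCF to a directory."""
    cfg = cfg or SimConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference, truth = simulate_truth(cfg)
    fasta = out / "reference.fa"
    with open(fasta, "w") as fh:
        fh.write(f">{cfg.chrom}\n")
        seq = bytes(reference).decode()
        for i in range(0, len(seq), 80):
            fh.write(seq[i:i + 80] + "\n")
    pysam.faidx(str(fasta))
    bam = out / "reads.bam"
    n_reads = simulate_reads(reference, truth, cfg, bam)
    truth_vcf = out / "truth.vcf"
    write_sv_vcf(truth, cfg, truth_vcf)
    rng = np.random.default_rng(cfg.rng_seed + 2)
    calls = make_caller_vcf(truth, cfg, rng)
    caller_vcf = out / "calls.vcf"
    write_sv_vcf(calls, cfg, caller_vcf)
    return {"reference": fasta, "bam": bam, "truth_vcf": truth_vcf,
            "caller_vcf": caller_vcf, "truth": truth, "calls": calls,
            "n_reads": n_reads, "config": cfg}


__all__ = ["SimConfig", "simulate_truth", "simulate_reads", "make_caller_vcf",
           "write_sv_vcf", "simulate_dataset"]
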