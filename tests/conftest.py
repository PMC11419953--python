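"""Shared fixtures: tiny hand-built SAM/VCF files and simulated datasets.

Everything is generated at test time; heavyweight artifacts (the trained
benchmark model) are session-scoped so several tests can share one
training run.
"""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from csvfilt.formats_io import SVRecord


@pytest.fixture(scope="session")
def tiny_bam(tmp_path_factory):
    """Hand-written 6-read BAM on a 10 kb contig, sorted and indexed."""
    d = tmp_path_factory.mktemp("tiny_bam")
    sam = d / "tiny.sam"
    reads = [
        # name, flag, pos(1-based), mapq, cigar
        ("r_a", 0, 96, 60, "10M"),
        ("r_b", 0, 101, 60, "5M2I3M"),
        ("r_c", 0, 101, 10, "10M"),          # low mapq
        ("r_d", 256, 103, 60, "10M"),        # secondary
        ("r_e", 0, 111, 60, "4M1D4M"),
        ("r_f", 0, 5000, 60, "10S4M"),
    ]
    with open(sam, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chrT\tLN:10000\n")
        for name, flag, pos, mapq, cigar in reads:
            qlen = sum(int(n) for n, c in
                       __import__("re").findall(r"(\d+)([MIS=X])", cigar))
            fh.write(f"{name}\t{flag}\tchrT\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t"
                     f"{'A' * qlen}\t*\n")
    bam = d / "tiny.bam"
    pysam.sort("-o", str(bam), str(sam))
    pysam.index(str(bam))
    return bam


@pytest.fixture(scope="session")
def tiny_vcf(tmp_path_factory):
    """Hand-written VCF: 2 INS + 1 DEL + 1 BND, mixed SVLEN/END encodings."""
    d = tmp_path_factory.mktemp("tiny_vcf")
    path = d / "tiny.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chrT,length=10000>\n"
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="l">\n'
        '##INFO=<ID=END,Number=1,Type=Integer,Description="e">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chrT\t1000\tins1\tN\t<INS>\t.\tPASS\tSVTYPE=INS;SVLEN=120\n"
        "chrT\t2000\tdel1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=2300\n"
        "chrT\t3000\tbnd1\tN\tN[chrT:5000[\t.\tPASS\tSVTYPE=BND\n"
        "chrT\t4000\tins2\tN\t<INS>\t.\tPASS\tSVTYPE=INS;SVLEN=80\n"
    )
    return path


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """Default-scale simulated dataset (2 Mb, 60 INS + 60 DEL, seed 17)."""
    from csvfilt.simulate import SimConfig, simulate_dataset

    d = tmp_path_factory.mktemp("sim")
    return simulate_dataset(d, SimConfig())


@pytest.fixture(scope="session")
def trained_benchmark(tmp_path_factory):
    """One full benchmark run (images, trained model, filtered VCF) shared
    by the end-to-end tests: simulator benchmark preset, seed 17."""
    from csvfilt.pipeline import benchmark_sim_config, run_benchmark
    from csvfilt.training import TrainConfig

    work = tmp_path_factory.mktemp("bench")
    result = run_benchmark(
        work,
        sim_cfg=benchmark_sim_config(17),
        train_cfg=TrainConfig(epochs=10, rng_seed=17),
        seed=17,
    )
    return {"work": work, "result": result}


def make_sv(svtype="DEL", pos=1001, svlen=300, chrom="chrT", id_="sv1", source="truth"):
    end = pos + svlen if svtype == "DEL" else pos
    return SVRecord(id=id_, chrom=chrom, pos=pos, end=end, svtype=svtype,
                    svlen=svlen, source=source)
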