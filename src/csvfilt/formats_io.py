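"""VCF / BAM input-output and coordinate conventions.

Everything downstream of this module works in 0-based half-open
coordinates (the BAM native convention); conversion to and from the
1-based inclusive VCF convention happens here and nowhere else.
"""

from __future__ import annotations

import gzip
import logging
import os
import re
from dataclasses import dataclass, field, replace

import pysam

logger = logging.getLogger(__name__)

SV_TYPES = ("INS", "DEL", "NEG")

#: CIGAR operation alphabet, in SAM numeric-code order.
CIGAR_CODES = "MIDNSHP=X"
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

#: codes that consume reference bases (used for read reference span)
REF_CONSUMING = frozenset("MDN=X")


@dataclass(frozen=True)
class SVRecord:
    """One structural-variant (or generated negative) site.

    ``pos``/``end`` follow the VCF convention: 1-based, inclusive.  For
    insertions ``end == pos`` (point event); the extent of the event is
    carried by ``svlen``.
    """

    id: str
    chrom: str
    pos: int
    end: int
    svtype: str
    svlen: int
    source: str = "truth"
    ordinal: int = -1  # body-line index in the source VCF, -1 if not from a file

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"svtype must be one of {SV_TYPES}, got {self.svtype!r}")
        if self.svlen <= 0:
            raise ValueError(f"svlen must be positive, got {self.svlen}")
        if self.end < self.pos:
            raise ValueError(f"end ({self.end}) < pos ({self.pos})")
        if self.svtype == "NEG" and self.source != "generated":
            raise ValueError("NEG records can only come from source='generated'")


@dataclass(frozen=True)
class GenomicRegion:
    """0-based half-open interval on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CigarAlignment:
    """One read's placement plus its parsed CIGAR operation list.

    ``b`` is the 0-based reference start of the alignment.
    """

    read_name: str
    chrom: str
    b: int
    ops: tuple[tuple[str, int], ...]
    is_primary: bool = True
    is_mapped: bool = True

    def __post_init__(self) -> None:
        for code, length in self.ops:
            if code not in CIGAR_CODES:
                raise ValueError(f"invalid CIGAR code {code!r}")
            if length < 1:
                raise ValueError(f"CIGAR length must be >= 1, got {length}")
        if self.is_mapped and not self.ops:
            raise ValueError("mapped read must have a non-empty CIGAR")


def parse_cigar(cigar_text: str) -> list[tuple[str, int]]:
    """Parse a SAM CIGAR string into an ordered ``(code, length)`` list.

    ``"*"`` (no CIGAR available) yields an empty list.  All nine operation
    codes are accepted; anything outside the grammar is a hard error.
    """
    if cigar_text == "*":
        return []
    ops: list[tuple[str, int]] = []
    pos = 0
    for m in _CIGAR_RE.finditer(cigar_text):
        if m.start() != pos:
            raise ValueError(f"invalid CIGAR {cigar_text!r} at offset {pos}")
        length = int(m.group(1))
        if length == 0:
            raise ValueError(f"zero-length CIGAR operation in {cigar_text!r}")
        ops.append((m.group(2), length))
        pos = m.end()
    if pos != len(cigar_text) or not ops:
        raise ValueError(f"invalid CIGAR string {cigar_text!r}")
    return ops


def cigar_to_string(ops: list[tuple[str, int]] | tuple[tuple[str, int], ...]) -> str:
    """Inverse of :func:`parse_cigar` (empty ops serialize to ``"*"``)."""
    if not ops:
        return "*"
    return "".join(f"{length}{code}" for code, length in ops)


def reference_span(ops) -> int:
    """Number of reference bases consumed by a CIGAR operation list."""
    return sum(length for code, length in ops if code in REF_CONSUMING)


def _svlen_from_record(rec: "pysam.VariantRecord", svtype: str) -> int | None:
    """SVLEN precedence: |SVLEN| INFO, else END-POS (DEL), else allele-length delta."""
    svlen = rec.info.get("SVLEN")
    if svlen is not None:
        if isinstance(svlen, (tuple, list)):
            svlen = svlen[0]
        if svlen is not None and int(svlen) != 0:
            return abs(int(svlen))
    if svtype == "DEL" and rec.stop is not None and rec.stop > rec.pos:
        return rec.stop - rec.pos
    if rec.alts:
        alt = rec.alts[0]
        if alt and not alt.startswith("<") and rec.ref:
            delta = abs(len(alt) - len(rec.ref))
            if delta > 0:
                return delta
    return None


def read_sv_vcf(path: str | os.PathLike, allowed_types: set[str] = frozenset({"INS", "DEL"})) -> list[SVRecord]:
    """Read SV records from a VCF, reconstructing lengths from SVLEN/END/alleles.

    Records whose SVTYPE is outside ``allowed_types`` are skipped; a DEL
    with no recoverable length is skipped with a warning.  Input order is
    preserved.  ``ordinal`` on each returned record is the index of its
    line among all body lines of the file, which lets
    :func:`write_filtered_vcf` pair decisions back to lines.
    """
    records: list[SVRecord] = []
    with pysam.VariantFile(os.fspath(path)) as vf:
        for ordinal, rec in enumerate(vf):
            svtype = rec.info.get("SVTYPE")
            if isinstance(svtype, (tuple, list)):
                svtype = svtype[0]
            if svtype not in allowed_types:
                continue
            svlen = _svlen_from_record(rec, svtype)
            if svlen is None:
                logger.warning(
                    "skipping %s record at %s:%d: no SVLEN, END or sequence alleles",
                    svtype, rec.chrom, rec.pos,
                )
                continue
            pos = rec.pos  # pysam .pos is 1-based
            if svtype == "DEL":
                end = pos + svlen
            else:  # INS and NEG are treated as point/position events
                end = pos
            rid = rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{pos}:{svtype}:{ordinal}"
            records.append(
                SVRecord(id=rid, chrom=rec.chrom, pos=pos, end=max(end, pos),
                         svtype=svtype, svlen=svlen,
                         source="generated" if svtype == "NEG" else "caller",
                         ordinal=ordinal)
            )
    return records


def fetch_alignments(
    bam: str | os.PathLike | pysam.AlignmentFile,
    region: GenomicRegion,
    min_mapq: int = 20,
    primary_only: bool = True,
) -> list[CigarAlignment]:
    """Fetch mapped reads overlapping ``region`` from an indexed BAM.

    Results are sorted by reference start then read name, so the output is
    deterministic for a fixed file and region.
    """
    own = not isinstance(bam, pysam.AlignmentFile)
    af = pysam.AlignmentFile(os.fspath(bam)) if own else bam
    try:
        if not af.has_index():
            raise FileNotFoundError(
                f"BAM index not found for {af.filename.decode()}; expected "
                f"{af.filename.decode()}.bai (run samtools index)"
            )
        out: list[CigarAlignment] = []
        for read in af.fetch(region.chrom, region.start, region.end):
            if read.is_unmapped or read.cigartuples is None:
                continue
            if read.mapping_quality < min_mapq:
                continue
            if primary_only and (read.is_secondary or read.is_supplementary):
                continue
            ops = tuple((CIGAR_CODES[code], length) for code, length in read.cigartuples)
            out.append(
                CigarAlignment(
                    read_name=read.query_name,
                    chrom=region.chrom,
                    b=read.reference_start,
                    ops=ops,
                    is_primary=not (read.is_secondary or read.is_supplementary),
                    is_mapped=True,
                )
            )
        out.sort(key=lambda a: (a.b, a.read_name))
        return out
    finally:
        if own:
            af.close()


def _open_text(path):
    raw = open(path, "rb")
    if raw.read(2) == b"\x1f\x8b":
        raw.seek(0)
        return gzip.open(raw, "rt")
    raw.seek(0)
    return open(path, "rt")


def write_filtered_vcf(input_vcf, decisions, out_path, provenance: str = "csvfilt") -> None:
    """Write a filtered copy of ``input_vcf`` keeping records whose decision says keep.

    ``decisions`` is an iterable of objects with ``record_id`` and ``keep``
    attributes covering every INS/DEL record of the input (by id).  Record
    lines are copied byte-identically; the only header change is one added
    provenance line.  Records that are not INS/DEL SVs (or whose length is
    unrecoverable) are passed through untouched.
    """
    keep_by_id = {d.record_id: d.keep for d in decisions}
    records = read_sv_vcf(input_vcf, allowed_types={"INS", "DEL"})
    keep_by_ordinal: dict[int, bool] = {}
    for rec in records:
        if rec.id not in keep_by_id:
            raise KeyError(f"no filter decision for record {rec.id!r}")
        keep_by_ordinal[rec.ordinal] = keep_by_id[rec.id]

    with _open_text(input_vcf) as src, open(out_path, "wt") as dst:
        ordinal = 0
        for line in src:
            if line.startswith("##"):
                dst.write(line)
            elif line.startswith("#"):
                dst.write(f"##csvfilt_filter={provenance}\n")
                dst.write(line)
            else:
                if keep_by_ordinal.get(ordinal, True):
                    dst.write(line)
                ordinal += 1


__all__ = [
    "SVRecord", "GenomicRegion", "CigarAlignment", "SV_TYPES", "CIGAR_CODES",
    "parse_cigar", "cigar_to_string", "reference_span",
    "read_sv_vcf", "fetch_alignments", "write_filtered_vcf",
]
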