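"""Multi-level grayscale image encoding of SV sites from CIGAR strings.

One image per candidate site.  Reads overlapping the (extended) site are
laid out one per row; along the x-axis every CIGAR operation of a read
draws ``length`` consecutive pixels, colored by operation: M, I, D and S
each get their own grayscale level, while N/P/H/=/X (and the offset of a
read's start from the leftmost read) are drawn as 0.  Insertion runs
therefore show up as bright horizontal bars at INS sites, deletion runs
at DEL sites, and soft clips at breakpoints — the signal the classifier
learns.  The raw variable-size grid is finally resized to a fixed
224 x 224 canvas.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pysam

from .formats_io import CigarAlignment, GenomicRegion, SVRecord, fetch_alignments

logger = logging.getLogger(__name__)

CANVAS = 224
_ENCODED_CODES = "MIDS"


@dataclass(frozen=True)
class GrayscaleMap:
    """Grayscale level per encoded CIGAR operation; all other codes map to 0."""

    level_M: int = 63
    level_I: int = 127
    level_D: int = 191
    level_S: int = 255

    def __post_init__(self):
        levels = self.as_dict()
        for code, lv in levels.items():
            if not (0 < lv <= 255):
                raise ValueError(f"level_{code}={lv} outside (0, 255]")
        if len(set(levels.values())) != 4:
            raise ValueError("the four grayscale levels must be pairwise distinct")

    def as_dict(self) -> dict[str, int]:
        return {"M": self.level_M, "I": self.level_I, "D": self.level_D, "S": self.level_S}

    def level_set(self) -> set[int]:
        return {0, *self.as_dict().values()}


@dataclass(frozen=True)
class RawSiteImage:
    """Variable-size grid: one row per selected read, columns from b_min."""

    pixels: np.ndarray  # uint8, shape (height, width)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class EncodedImage:
    """224 x 224 grayscale image with optional class label."""

    pixels: np.ndarray  # uint8, (224, 224)
    site_id: str = ""
    label: str | None = None

    def __post_init__(self):
        if self.pixels.shape != (CANVAS, CANVAS):
            raise ValueError(f"expected {CANVAS}x{CANVAS}, got {self.pixels.shape}")


@dataclass(frozen=True)
class EncoderConfig:
    extension: int = 1000          # bp added on each side of the site
    grayscale_map: GrayscaleMap = field(default_factory=GrayscaleMap)
    max_rows: int = 512            # coverage cap: deterministic decimation above this
    resize_method: str = "nearest"  # or "bilinear"
    min_mapq: int = 20
    primary_only: bool = True

    def __post_init__(self):
        if self.extension < 0:
            raise ValueError("extension must be >= 0")
        if self.max_rows < 1:
            raise ValueError("max_rows must be >= 1")
        if self.resize_method not in ("nearest", "bilinear"):
            raise ValueError("resize_method must be 'nearest' or 'bilinear'")


def extend_region(site: SVRecord, extension: int, chrom_length: int | None = None) -> GenomicRegion:
    """Extend a site by ``extension`` bp on each side, 0-based half-open.

    DEL/NEG sites span [pos-1, end); INS sites are points at pos-1 whose
    window is [pos-1, pos).  Clipped at the chromosome bounds.
    """
    start = site.pos - 1 - extension
    if site.svtype == "INS":
        end = site.pos + extension
    else:
        end = site.end + extension
    start = max(start, 0)
    if chrom_length is not None:
        end = min(end, chrom_length)
    if end <= start:  # degenerate after clipping; keep a 1-bp window
        end = start + 1
    return GenomicRegion(chrom=site.chrom, start=start, end=end)


def compute_b_min(reads: list[CigarAlignment]) -> int:
    """Minimum reference start over the selected reads."""
    if not reads:
        raise ValueError("compute_b_min requires at least one read")
    return min(r.b for r in reads)


def read_extent(read: CigarAlignment) -> int:
    """Number of image columns a read draws: the sum of all its op lengths.

    Every operation (including insertions and clips, and the zero-drawn
    N/P/H/=/X) consumes columns, so read geometry is preserved on the
    x-axis.
    """
    if not read.ops:
        raise ValueError("read has an empty CIGAR")
    return sum(length for _, length in read.ops)


def encode_row(read: CigarAlignment, b_min: int, width: int, gmap: GrayscaleMap) -> np.ndarray:
    """Encode one read into one pixel row of a raw site image."""
    if read.b < b_min:
        raise ValueError("read starts before b_min")
    levels = gmap.as_dict()
    row = np.zeros(width, dtype=np.uint8)
    col = read.b - b_min
    end_col = col + read_extent(read)
    if end_col > width:
        raise ValueError(f"row needs {end_col} columns but width is {width}")
    for code, length in read.ops:
        level = levels.get(code, 0)
        if level:
            row[col:col + length] = level
        col += length
    return row


def _select_rows(reads: list[CigarAlignment], max_rows: int) -> list[CigarAlignment]:
    ordered = sorted(reads, key=lambda r: (r.b, r.read_name))
    if len(ordered) <= max_rows:
        return ordered
    k = -(-len(ordered) // max_rows)  # ceil division: keep every k-th read
    return ordered[::k]


def encode_raw_image(reads: list[CigarAlignment], cfg: EncoderConfig) -> RawSiteImage:
    """Stack one encoded row per read (ordered by start, then name)."""
    if not reads:
        raise ValueError("cannot encode an image from zero reads")
    rows = _select_rows(reads, cfg.max_rows)
    b_min = compute_b_min(rows)
    width = max((r.b - b_min) + read_extent(r) for r in rows)
    pixels = np.stack([encode_row(r, b_min, width, cfg.grayscale_map) for r in rows])
    return RawSiteImage(pixels=pixels)


def _resize_nearest(pixels: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    h, w = pixels.shape
    ri = np.minimum(((np.arange(out_h) + 0.5) * h / out_h).astype(np.int64), h - 1)
    ci = np.minimum(((np.arange(out_w) + 0.5) * w / out_w).astype(np.int64), w - 1)
    return pixels[np.ix_(ri, ci)]


def resize_to_canvas(raw: RawSiteImage, cfg: EncoderConfig | None = None,
                     site_id: str = "", label: str | None = None) -> EncodedImage:
    """Stretch/compress a raw image to the fixed 224 x 224 canvas.

    Nearest-neighbor (default) keeps pixel values inside the discrete
    grayscale level set; bilinear interpolation is available as an option.
    """
    cfg = cfg or EncoderConfig()
    if raw.pixels.size == 0:
        raise ValueError("empty raw image")
    if cfg.resize_method == "nearest":
        out = _resize_nearest(raw.pixels, CANVAS, CANVAS)
    else:
        from PIL import Image

        out = np.asarray(
            Image.fromarray(raw.pixels, mode="L").resize((CANVAS, CANVAS), Image.BILINEAR)
        )
    return EncodedImage(pixels=out.astype(np.uint8), site_id=site_id, label=label)


def encode_site(
    bam: str | os.PathLike | pysam.AlignmentFile,
    site: SVRecord,
    cfg: EncoderConfig | None = None,
    chrom_length: int | None = None,
) -> EncodedImage | None:
    """Encode one site from a BAM; returns None for zero-coverage sites."""
    cfg = cfg or EncoderConfig()
    own = not isinstance(bam, pysam.AlignmentFile)
    af = pysam.AlignmentFile(os.fspath(bam)) if own else bam
    try:
        if chrom_length is None:
            chrom_length = af.get_reference_length(site.chrom)
        region = extend_region(site, cfg.extension, chrom_length)
        reads = fetch_alignments(af, region, min_mapq=cfg.min_mapq,
                                 primary_only=cfg.primary_only)
        if not reads:
            logger.info("zero coverage at %s %s:%d", site.svtype, site.chrom, site.pos)
            return None
        raw = encode_raw_image(reads, cfg)
        return resize_to_canvas(raw, cfg, site_id=site.id, label=site.svtype)
    finally:
        if own:
            af.close()


__all__ = [
    "CANVAS", "GrayscaleMap", "RawSiteImage", "EncodedImage", "EncoderConfig",
    "extend_region", "compute_b_min", "read_extent", "encode_row",
    "encode_raw_image", "resize_to_canvas", "encode_site",
]
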