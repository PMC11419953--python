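"""Image encoding: region extension, row layout, grayscale levels, resize."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csvfilt.encoder import (
    CANVAS,
    EncodedImage,
    EncoderConfig,
    GrayscaleMap,
    RawSiteImage,
    compute_b_min,
    encode_raw_image,
    encode_row,
    encode_site,
    extend_region,
    read_extent,
    resize_to_canvas,
)
from csvfilt.formats_io import CigarAlignment
from tests.conftest import make_sv

GMAP = GrayscaleMap()


def read(name, b, ops):
    return CigarAlignment(read_name=name, chrom="chrT", b=b, ops=tuple(ops))


class TestExtendRegion:
    def test_del_zero_extension_is_pure_coordinate_conversion(self):
        region = extend_region(make_sv("DEL", pos=1001, svlen=299), 0)
        assert (region.start, region.end) == (1000, 1300)

    def test_ins_window_from_svlen_not_end(self):
        region = extend_region(make_sv("INS", pos=500, svlen=1000), 200)
        assert (region.start, region.end) == (299, 700)

    def test_clipping_at_chromosome_edges(self):
        region = extend_region(make_sv("DEL", pos=51, svlen=100), 500, chrom_length=400)
        assert region.start == 0 and region.end == 400


class TestRowGeometry:
    def test_b_min(self):
        assert compute_b_min([read("a", 95, [("M", 5)]), read("b", 110, [("M", 5)]),
                              read("c", 100, [("M", 5)])]) == 95
        with pytest.raises(ValueError):
            compute_b_min([])

    @pytest.mark.parametrize("ops,extent", [
        ([("M", 5), ("I", 2), ("M", 3)], 10),
        ([("S", 10), ("M", 4)], 14),
        ([("M", 1)], 1),
        ([("N", 3), ("P", 2), ("H", 4), ("=", 1), ("X", 1)], 11),
    ])
    def test_every_op_consumes_columns(self, ops, extent):
        assert read_extent(read("r", 0, ops)) == extent

    def test_encode_row_manual_trace(self):
        # offset 2, then M3 D1 M2 with M=63, D=191 on width 8
        row = encode_row(read("r", 2, [("M", 3), ("D", 1), ("M", 2)]), 0, 8, GMAP)
        assert row.tolist() == [0, 0, 63, 63, 63, 191, 63, 63]

    def test_zero_mapped_codes_draw_zero_but_consume(self):
        row = encode_row(read("r", 0, [("M", 2), ("N", 3), ("M", 1)]), 0, 6, GMAP)
        assert row.tolist() == [63, 63, 0, 0, 0, 63]

    def test_width_overflow_is_hard_error(self):
        with pytest.raises(ValueError):
            encode_row(read("r", 0, [("M", 10)]), 0, 5, GMAP)


class TestRawImage:
    def test_two_read_composition(self):
        img = encode_raw_image(
            [read("a", 0, [("M", 4)]), read("b", 2, [("M", 4)])], EncoderConfig()
        )
        assert img.pixels.shape == (2, 6)
        assert img.pixels[0].tolist() == [63, 63, 63, 63, 0, 0]
        assert img.pixels[1].tolist() == [0, 0, 63, 63, 63, 63]

    def test_row_order_and_determinism(self):
        reads = [read("z", 5, [("M", 3)]), read("a", 5, [("M", 3)]),
                 read("m", 0, [("M", 3)])]
        a = encode_raw_image(reads, EncoderConfig())
        b = encode_raw_image(list(reversed(reads)), EncoderConfig())
        assert np.array_equal(a.pixels, b.pixels)
        assert a.pixels.shape[0] == 3

    def test_shift_invariance(self):
        reads = [read("a", 100, [("M", 4), ("D", 2), ("M", 4)]),
                 read("b", 103, [("S", 2), ("M", 6)])]
        shifted = [CigarAlignment(r.read_name, r.chrom, r.b + 7777, r.ops)
                   for r in reads]
        cfg = EncoderConfig()
        assert np.array_equal(encode_raw_image(reads, cfg).pixels,
                              encode_raw_image(shifted, cfg).pixels)

    def test_max_rows_decimation_is_deterministic(self):
        reads = [read(f"r{i:03d}", i, [("M", 5)]) for i in range(100)]
        cfg = EncoderConfig(max_rows=10)
        img = encode_raw_image(reads, cfg)
        assert img.pixels.shape[0] == 10
        assert np.array_equal(img.pixels, encode_raw_image(reads, cfg).pixels)


class TestResize:
    def test_identity_for_canvas_sized_input(self):
        pixels = np.random.default_rng(0).choice(
            [0, 63, 127, 191, 255], size=(CANVAS, CANVAS)).astype(np.uint8)
        out = resize_to_canvas(RawSiteImage(pixels))
        assert np.array_equal(out.pixels, pixels)

    def test_nearest_preserves_value_set(self):
        raw = RawSiteImage(np.array([[0, 63, 127, 191, 255]], dtype=np.uint8))
        out = resize_to_canvas(raw)
        assert set(np.unique(out.pixels)) <= {0, 63, 127, 191, 255}

    def test_constant_image_stays_constant(self):
        raw = RawSiteImage(np.full((10, 448), 63, dtype=np.uint8))
        assert np.all(resize_to_canvas(raw).pixels == 63)

    @given(st.integers(1, 40), st.integers(1, 600), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_pixel_alphabet_property(self, h, w, seed):
        levels = np.array([0, 63, 127, 191, 255], dtype=np.uint8)
        pixels = np.random.default_rng(seed).choice(levels, size=(h, w))
        out = resize_to_canvas(RawSiteImage(pixels))
        assert out.pixels.shape == (CANVAS, CANVAS)
        assert set(np.unique(out.pixels)) <= set(levels.tolist())


class TestEncodeSite:
    def test_zero_coverage_returns_none(self, tiny_bam):
        site = make_sv("DEL", pos=8001, svlen=100)
        assert encode_site(tiny_bam, site, EncoderConfig(extension=10)) is None

    def test_simulated_del_site_shows_deletion_level(self, sim_dataset):
        cfg = EncoderConfig()
        dels = [t for t in sim_dataset["truth"] if t.svtype == "DEL"]
        img = encode_site(sim_dataset["bam"], dels[0], cfg)
        assert isinstance(img, EncodedImage)
        assert (img.pixels == cfg.grayscale_map.level_D).sum() > 0

    def test_simulated_ins_site_shows_insertion_level(self, sim_dataset):
        cfg = EncoderConfig()
        ins = [t for t in sim_dataset["truth"] if t.svtype == "INS"]
        img = encode_site(sim_dataset["bam"], ins[0], cfg)
        assert (img.pixels == cfg.grayscale_map.level_I).sum() > 0

    def test_signature_signal_exceeds_matched_negative(self, sim_dataset):
        """At nearly all sites, the D-level mass at a DEL site (I at INS)
        exceeds that at generated negative sites."""
        from csvfilt.negatives import NegativeSamplingConfig, estimate_lambda, \
            sample_negative_sites

        cfg = EncoderConfig()
        truth = sim_dataset["truth"]
        model = estimate_lambda([t.svlen for t in truth])
        negs = sample_negative_sites(
            truth, {"chr1": sim_dataset["config"].chrom_length}, model,
            NegativeSamplingConfig(n_target=30, rng_seed=2))
        neg_counts = {"DEL": [], "INS": []}
        for n in negs:
            img = encode_site(sim_dataset["bam"], n, cfg)
            if img is not None:
                neg_counts["DEL"].append((img.pixels == cfg.grayscale_map.level_D).sum())
                neg_counts["INS"].append((img.pixels == cfg.grayscale_map.level_I).sum())
        wins = trials = 0
        for svtype, level in (("DEL", cfg.grayscale_map.level_D),
                              ("INS", cfg.grayscale_map.level_I)):
            sites = [t for t in truth if t.svtype == svtype][:20]
            ref = np.median(neg_counts[svtype])
            for site in sites:
                img = encode_site(sim_dataset["bam"], site, cfg)
                trials += 1
                wins += (img.pixels == level).sum() > ref
        assert wins / trials >= 0.95

    def test_grayscale_map_validation(self):
        with pytest.raises(ValueError):
            GrayscaleMap(level_M=63, level_I=63, level_D=191, level_S=255)
        with pytest.raises(ValueError):
            GrayscaleMap(level_M=0)
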