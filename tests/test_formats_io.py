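"""VCF/BAM I/O, CIGAR parsing and coordinate conventions."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csvfilt.filtering import FilterDecision
from csvfilt.formats_io import (
    CIGAR_CODES,
    CigarAlignment,
    GenomicRegion,
    SVRecord,
    cigar_to_string,
    fetch_alignments,
    parse_cigar,
    read_sv_vcf,
    write_filtered_vcf,
)
from csvfilt.model import ClassProbabilities


class TestParseCigar:
    @pytest.mark.parametrize("text,expected", [
        ("5M2I3M", [("M", 5), ("I", 2), ("M", 3)]),
        ("*", []),
        ("10S4M1D4M3H", [("S", 10), ("M", 4), ("D", 1), ("M", 4), ("H", 3)]),
        ("7=1X2N3P1M", [("=", 7), ("X", 1), ("N", 2), ("P", 3), ("M", 1)]),
    ])
    def test_grammar(self, text, expected):
        assert parse_cigar(text) == expected

    @pytest.mark.parametrize("bad", ["5Q", "M5", "0M", "5M3", "", "5m"])
    def test_invalid_is_hard_error(self, bad):
        with pytest.raises(ValueError):
            parse_cigar(bad)

    @given(st.lists(st.tuples(st.sampled_from(CIGAR_CODES),
                              st.integers(min_value=1, max_value=500)),
                    min_size=1, max_size=20))
    @settings(max_examples=200, deadline=None)
    def test_roundtrip(self, ops):
        assert parse_cigar(cigar_to_string(ops)) == ops


class TestSVRecord:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SVRecord(id="x", chrom="c", pos=10, end=5, svtype="DEL", svlen=5)
        with pytest.raises(ValueError):
            SVRecord(id="x", chrom="c", pos=10, end=10, svtype="INS", svlen=0)
        with pytest.raises(ValueError):
            SVRecord(id="x", chrom="c", pos=10, end=12, svtype="NEG", svlen=3,
                     source="truth")

    def test_region_invariant(self):
        with pytest.raises(ValueError):
            GenomicRegion(chrom="c", start=5, end=5)


class TestReadSvVcf:
    def test_type_filter_and_lengths(self, tiny_vcf):
        recs = read_sv_vcf(tiny_vcf, allowed_types={"INS", "DEL"})
        assert [r.id for r in recs] == ["ins1", "del1", "ins2"]
        del1 = recs[1]
        # svlen reconstructed from END - POS when SVLEN is absent
        assert del1.svlen == 300 and del1.end == 2300
        assert recs[0].svlen == 120 and recs[0].end == recs[0].pos

    def test_allowed_types_restrict(self, tiny_vcf):
        assert len(read_sv_vcf(tiny_vcf, allowed_types={"INS"})) == 2
        assert read_sv_vcf(tiny_vcf, allowed_types=set()) == []


class TestFetchAlignments:
    def test_sorted_and_filtered(self, tiny_bam):
        region = GenomicRegion(chrom="chrT", start=90, end=130)
        reads = fetch_alignments(tiny_bam, region, min_mapq=20, primary_only=True)
        # low-mapq r_c and secondary r_d are excluded; order by start then name
        assert [r.read_name for r in reads] == ["r_a", "r_b", "r_e"]
        assert [r.b for r in reads] == [95, 100, 110]
        assert reads[1].ops == (("M", 5), ("I", 2), ("M", 3))

    def test_empty_region(self, tiny_bam):
        assert fetch_alignments(tiny_bam, GenomicRegion("chrT", 9000, 9100)) == []

    def test_mapq_threshold_relaxed(self, tiny_bam):
        region = GenomicRegion(chrom="chrT", start=90, end=130)
        names = {r.read_name for r in fetch_alignments(tiny_bam, region, min_mapq=0)}
        assert "r_c" in names

    def test_deterministic(self, tiny_bam):
        region = GenomicRegion(chrom="chrT", start=90, end=130)
        assert fetch_alignments(tiny_bam, region) == fetch_alignments(tiny_bam, region)


def _decisions(records, drop_ids=()):
    third = ClassProbabilities(1 / 3, 1 / 3, 1 / 3)
    return [
        FilterDecision(r.id, "NEG" if r.id in drop_ids else r.svtype, third,
                       keep=r.id not in drop_ids,
                       reason="predicted_negative" if r.id in drop_ids else "passed")
        for r in records
    ]


class TestWriteFilteredVcf:
    def test_all_keep_roundtrip(self, tiny_vcf, tmp_path):
        records = read_sv_vcf(tiny_vcf)
        out = tmp_path / "keep.vcf"
        write_filtered_vcf(tiny_vcf, _decisions(records), out)
        assert read_sv_vcf(out) == [
            # ordinal shifts are not expected: no record line was removed
            r for r in read_sv_vcf(tiny_vcf)
        ]
        # record lines are byte-identical; one provenance header line added
        original = [l for l in open(tiny_vcf) if not l.startswith("#")]
        written = [l for l in open(out) if not l.startswith("#")]
        assert written == original
        assert sum(l.startswith("##csvfilt_filter=") for l in open(out)) == 1

    def test_drop_subset_preserves_order(self, tiny_vcf, tmp_path):
        records = read_sv_vcf(tiny_vcf)
        out = tmp_path / "drop.vcf"
        write_filtered_vcf(tiny_vcf, _decisions(records, drop_ids={"del1"}), out)
        kept = read_sv_vcf(out)
        assert [r.id for r in kept] == ["ins1", "ins2"]
        # the BND record is passed through untouched
        assert any("bnd1" in l for l in open(out))

    def test_all_drop_leaves_header_plus_passthrough(self, tiny_vcf, tmp_path):
        records = read_sv_vcf(tiny_vcf)
        out = tmp_path / "none.vcf"
        write_filtered_vcf(tiny_vcf, _decisions(records, drop_ids={r.id for r in records}), out)
        assert read_sv_vcf(out) == []

    def test_missing_decision_is_hard_error(self, tiny_vcf, tmp_path):
        records = read_sv_vcf(tiny_vcf)
        with pytest.raises(KeyError):
            write_filtered_vcf(tiny_vcf, _decisions(records)[:-1], tmp_path / "x.vcf")
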