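"""I/O round-trips, SV typing and simple/non-simple classification."""

import itertools
import random

import pytest

from svkit.records import Breakpoint, SVRecord, classify_sv_type
from svkit import sv_io
from svkit.simulate import make_toy_genome, simulate_simple_cohort

from conftest import make_sv


class TestClassifySvType:
    @pytest.mark.parametrize(
        "o1,o2,expected",
        [
            ("+", "-", "deletion_type"),
            ("-", "+", "td_type"),
            ("+", "+", "head_to_head"),
            ("-", "-", "tail_to_tail"),
        ],
    )
    def test_orientation_grid(self, o1, o2, expected):
        bp1 = Breakpoint("chr1", 1000, o1)
        bp2 = Breakpoint("chr1", 5000, o2)
        assert classify_sv_type(bp1, bp2) == expected

    def test_interchromosomal_always_translocation(self):
        for o1, o2 in itertools.product("+-", repeat=2):
            assert (
                classify_sv_type(
                    Breakpoint("chr1", 1000, o1), Breakpoint("chr2", 2000, o2)
                )
                == "translocation"
            )

    def test_canonicalization_orders_breakends(self):
        r = make_sv("x", "chr1", 5000, "-", "chr1", 1000, "+")
        assert (r.bp1.pos, r.bp2.pos) == (1000, 5000)
        # orientations travel with their breakends under the swap
        assert (r.bp1.orient, r.bp2.orient) == ("+", "-")
        assert r.svtype == "deletion_type"
        r2 = make_sv("y", "chr2", 7, "+", "chr1", 9, "-")
        assert r2.bp1.chrom == "chr1"

    def test_size_only_for_intra(self):
        assert make_sv("a", "chr1", 100, "+", "chr1", 600, "-").size == 500
        assert make_sv("b", "chr1", 100, "+", "chr2", 600, "-").size is None


class TestBedpe:
    def test_toy_round_trip_preserves_ids_and_fields(self, tmp_path):
        recs = [
            make_sv("sv1", "chr1", 100, "+", "chr1", 900, "-", mh=5),
            make_sv("sv2", "chr1", 200, "-", "chr1", 700, "+", ins=12),
            make_sv("sv3", "chr1", 50, "+", "chr2", 60, "-"),
        ]
        p = tmp_path / "t.bedpe"
        sv_io.write_bedpe(recs, p)
        back = sv_io.read_bedpe(p)
        assert [r.id for r in back] == ["sv1", "sv2", "sv3"]
        for a, b in zip(recs, back):
            assert (a.bp1, a.bp2, a.svtype, a.mh_len, a.ins_len) == (
                b.bp1, b.bp2, b.svtype, b.mh_len, b.ins_len
            )

    def test_swapped_coordinates_are_canonicalized(self, tmp_path):
        p = tmp_path / "t.bedpe"
        p.write_text("chr1\t5000\t5001\tchr1\t1000\t1001\tsv\t10\t-\t+\n")
        (r,) = sv_io.read_bedpe(p)
        assert r.bp1.pos == 1000 and r.bp2.pos == 5000

    def test_missing_mh_defaults_to_zero(self, tmp_path):
        p = tmp_path / "t.bedpe"
        p.write_text("chr1\t1000\t1001\tchr1\t5000\t5001\tsv\t10\t+\t-\n")
        (r,) = sv_io.read_bedpe(p)
        assert r.mh_len == 0 and r.ins_len == 0

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "t.bedpe"
        p.write_text("chr1\t1\t2\tchr1\t5\t6\tsv\t1\t+\n")
        with pytest.raises(sv_io.ParseError, match=":1"):
            sv_io.read_bedpe(p)

    def test_unknown_strand_symbol_is_an_error(self, tmp_path):
        p = tmp_path / "t.bedpe"
        p.write_text("chr1\t1\t2\tchr1\t5\t6\tsv\t1\t+\t*\n")
        with pytest.raises(sv_io.ParseError, match="strand"):
            sv_io.read_bedpe(p)

    def test_near_duplicates_merged_keeping_max_qual(self):
        a = make_sv("a", "chr1", 1000, "+", "chr1", 5000, "-", qual=10)
        b = make_sv("b", "chr1", 1004, "+", "chr1", 4997, "-", qual=30)
        merged = sv_io.dedup_records([a, b])
        assert len(merged) == 1 and merged[0].qual == 30

    def test_random_round_trip_all_fields(self, tmp_path, genome):
        cohort = simulate_simple_cohort(genome, n_samples=2, seed=11)
        p = tmp_path / "c.bedpe"
        sv_io.write_bedpe(cohort.svs, p)
        back = sv_io.read_bedpe(p)
        key = lambda r: r.id
        assert len(back) == len(cohort.svs)
        for a, b in zip(sorted(cohort.svs, key=key), sorted(back, key=key)):
            assert (a.bp1, a.bp2, a.mh_len, a.ins_len, a.sample, a.qual) == (
                b.bp1, b.bp2, b.mh_len, b.ins_len, b.sample, b.qual
            )


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
    '##INFO=<ID=MATEID,Number=1,Type=String,Description="m">\n'
    '##INFO=<ID=HOMLEN,Number=1,Type=Integer,Description="h">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


class TestVcfBnd:
    def _write(self, tmp_path, body):
        p = tmp_path / "t.vcf"
        p.write_text(VCF_HEADER + body)
        return p

    def test_translocation_pair(self, tmp_path):
        p = self._write(
            tmp_path,
            "chr1\t1000\ta:1\tN\tN[chr2:2000[\t60\t.\tSVTYPE=BND;MATEID=a:2\n"
            "chr2\t2000\ta:2\tN\t]chr1:1000]N\t60\t.\tSVTYPE=BND;MATEID=a:1\n",
        )
        (r,) = sv_io.read_vcf_bnd(p)
        assert r.svtype == "translocation"
        assert (r.bp1.chrom, r.bp1.pos, r.bp1.orient) == ("chr1", 999, "+")
        assert (r.bp2.chrom, r.bp2.pos, r.bp2.orient) == ("chr2", 1999, "-")

    def test_reverse_bracket_gives_td_type(self, tmp_path):
        p = self._write(
            tmp_path,
            "chr1\t1000\tb:1\tN\t]chr1:5000]N\t50\t.\tSVTYPE=BND;MATEID=b:2;HOMLEN=4\n"
            "chr1\t5000\tb:2\tN\tN[chr1:1000[\t50\t.\tSVTYPE=BND;MATEID=b:1;HOMLEN=4\n",
        )
        (r,) = sv_io.read_vcf_bnd(p)
        assert r.svtype == "td_type"
        assert (r.bp1.orient, r.bp2.orient) == ("-", "+")
        assert r.mh_len == 4

    def test_unpaired_mate_warns_and_drops(self, tmp_path):
        p = self._write(
            tmp_path,
            "chr1\t100\tc:1\tN\tN[chr1:900[\t10\t.\tSVTYPE=BND;MATEID=c:2\n",
        )
        with pytest.warns(UserWarning, match="unpaired"):
            recs = sv_io.read_vcf_bnd(p)
        assert recs == []

    def test_agrees_with_bedpe_on_paired_fixture(self, tmp_path):
        p = self._write(
            tmp_path,
            "chr1\t1001\td:1\tN\tN[chr1:5001[\t9\t.\tSVTYPE=BND;MATEID=d:2\n"
            "chr1\t5001\td:2\tN\t]chr1:1001]N\t9\t.\tSVTYPE=BND;MATEID=d:1\n",
        )
        (vr,) = sv_io.read_vcf_bnd(p)
        bp = tmp_path / "t.bedpe"
        bp.write_text("chr1\t1000\t1001\tchr1\t5000\t5001\td\t9\t+\t-\n")
        (br,) = sv_io.read_bedpe(bp)
        assert vr.svtype == br.svtype == "deletion_type"
        assert (vr.bp1.pos, vr.bp2.pos) == (br.bp1.pos, br.bp2.pos)


class TestSimpleStatus:
    def test_isolated_deletion_is_simple(self):
        svs = [make_sv("d", "chr1", 1000, "+", "chr1", 5000, "-")]
        (r,) = sv_io.classify_simple_status(svs)
        assert r.simple_status == "simple"

    def test_contained_breakend_makes_non_simple(self):
        svs = [
            make_sv("d", "chr1", 1000, "+", "chr1", 5000, "-"),
            make_sv("x", "chr1", 3000, "+", "chr1", 9000, "-"),
        ]
        out = {r.id: r.simple_status for r in sv_io.classify_simple_status(svs)}
        assert out["d"] == "non_simple"

    def test_translocations_always_non_simple(self):
        svs = [make_sv("t", "chr1", 100, "+", "chr2", 100, "-")]
        (r,) = sv_io.classify_simple_status(svs)
        assert r.simple_status == "non_simple"

    def test_mixed_samples_rejected(self):
        svs = [
            make_sv("a", "chr1", 10, "+", "chr1", 20, "-", sample="S1"),
            make_sv("b", "chr1", 30, "+", "chr1", 40, "-", sample="S2"),
        ]
        with pytest.raises(ValueError, match="mixed samples"):
            sv_io.classify_simple_status(svs)

    def test_order_invariant(self, genome):
        cohort = simulate_simple_cohort(genome, n_samples=1, seed=5)
        svs = cohort.svs
        ref = {
            r.id: r.simple_status for r in sv_io.classify_simple_status(list(svs))
        }
        rng = random.Random(0)
        for _ in range(3):
            shuffled = list(svs)
            rng.shuffle(shuffled)
            got = {
                r.id: r.simple_status
                for r in sv_io.classify_simple_status(shuffled)
            }
            assert got == ref


class TestTables:
    def test_overlapping_cn_segments_rejected(self, tmp_path):
        p = tmp_path / "cn.bed"
        p.write_text("chr1\t0\t100\t2\tS1\nchr1\t50\t200\t3\tS1\n")
        with pytest.raises(sv_io.ParseError, match="overlapping"):
            sv_io.read_cn_segments(p)

    def test_mixed_bin_widths_rejected_naming_offender(self, tmp_path):
        p = tmp_path / "cov.bedgraph"
        p.write_text("chr1\t0\t100\t1.0\nchr1\t100\t250\t1.0\n")
        with pytest.raises(sv_io.ParseError, match="chr1:100-250"):
            sv_io.read_coverage(p)

    def test_coverage_round_trip(self, tmp_path, flat_track):
        p = tmp_path / "cov.bedgraph"
        sv_io.write_coverage(flat_track, p)
        back = sv_io.read_coverage(p, sample="S1")
        assert back.bin_size == flat_track.bin_size
        assert back.mean("chr2", 0, 1_000_000) == 1.0

    def test_tsv_report_and_chrom_sizes(self, tmp_path):
        svs = sv_io.classify_simple_status(
            [make_sv("a", "chr1", 10, "+", "chr1", 500, "-")]
        )
        out = tmp_path / "r.tsv"
        sv_io.write_records(svs, out)
        lines = out.read_text().splitlines()
        assert lines[0].startswith("id\t") and "simple" in lines[1]
        cs = tmp_path / "c.sizes"
        cs.write_text("chr1\t1000\nchr2\t2000\n")
        assert sv_io.read_chrom_sizes(cs) == {"chr1": 1000, "chr2": 2000}
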