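import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from karyocourt import formats_io as fio


@pytest.fixture
def scaffolds():
    return fio.ScaffoldSet("asm", [("s1", 1000), ("s2", 2000)])


class TestPairs:
    def test_pair_type_filter(self, tmp_path, scaffolds):
        p = tmp_path / "x.pairs"
        p.write_text(
            "## pairs format v1.0\n"
            "r1\ts1\t10\ts2\t20\t+\t-\tUU\n"
            "r2\ts1\t11\ts2\t21\t+\t-\tMM\n"
            "r3\ts2\t12\ts1\t22\t+\t-\tUU\n")
        recs = list(fio.read_pairs(p, scaffolds))
        assert [r.read_id for r in recs] == ["r1", "r3"]

    def test_header_only_file_is_empty(self, tmp_path, scaffolds):
        p = tmp_path / "x.pairs"
        p.write_text("## pairs format v1.0\n#columns: ...\n")
        assert list(fio.read_pairs(p, scaffolds)) == []

    def test_out_of_range_position_rejected(self, tmp_path, scaffolds):
        p = tmp_path / "x.pairs"
        p.write_text("r1\ts1\t1000\ts2\t20\t+\t-\tUU\n")  # pos == L
        with pytest.raises(fio.FormatError, match="outside"):
            list(fio.read_pairs(p, scaffolds))

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "x.pairs"
        p.write_text("r1\ts1\t10\n")
        with pytest.raises(fio.FormatError, match=":1:"):
            list(fio.read_pairs(p))

    def test_unknown_scaffold_rejected(self, tmp_path, scaffolds):
        p = tmp_path / "x.pairs"
        p.write_text("r1\tsX\t10\ts2\t20\t+\t-\tUU\n")
        with pytest.raises(fio.FormatError, match="unknown scaffold"):
            list(fio.read_pairs(p, scaffolds))

    def test_canonical_order_enforced(self, tmp_path, scaffolds):
        p = tmp_path / "x.pairs"
        p.write_text("r1\ts2\t5\ts1\t999\t+\t-\tUU\n")
        (rec,) = fio.read_pairs(p, scaffolds)
        assert (rec.scaffold1, rec.pos1) == ("s1", 999)
        assert (rec.strand1, rec.strand2) == ("-", "+")

    @given(st.lists(
        st.tuples(st.sampled_from(["s1", "s2"]), st.integers(0, 999),
                  st.sampled_from(["s1", "s2"]), st.integers(0, 999)),
        max_size=30))
    def test_round_trip(self, tmp_path_factory, ends):
        scaffolds = fio.ScaffoldSet("asm", [("s1", 1000), ("s2", 1000)])
        recs = [
            fio.PairRecord(f"r{i}", a, pa, b, pb, "+", "-", "UU")
            for i, (a, pa, b, pb) in enumerate(ends)
        ]
        recs = [fio._canonical(r, scaffolds) for r in recs]
        p = tmp_path_factory.mktemp("pairs") / "x.pairs"
        fio.write_pairs(recs, p, scaffolds)
        back = list(fio.read_pairs(p, scaffolds))
        assert sorted(back) == sorted(recs)


class TestPaf:
    def test_valid_row(self, tmp_path):
        p = tmp_path / "x.paf"
        p.write_text("q\t100000\t0\t50000\t+\tt\t200000\t0\t50000\t49000\t50000\t60\n")
        (blk,) = fio.read_paf(p)
        assert blk.q_end - blk.q_start == 50000

    def test_short_block_dropped(self, tmp_path):
        p = tmp_path / "x.paf"
        p.write_text("q\t100000\t0\t5000\t+\tt\t200000\t0\t5000\t4900\t5000\t60\n")
        assert fio.read_paf(p) == []

    def test_truncated_row_rejected(self, tmp_path):
        p = tmp_path / "x.paf"
        p.write_text("q\t100000\t0\t50000\t+\tt\t200000\t0\n")
        with pytest.raises(fio.FormatError, match="8"):
            fio.read_paf(p)

    def test_non_integer_coordinate_rejected(self, tmp_path):
        p = tmp_path / "x.paf"
        p.write_text("q\t100000\tzero\t50000\t+\tt\t200000\t0\t50000\t49000\t50000\t60\n")
        with pytest.raises(fio.FormatError, match="non-integer"):
            fio.read_paf(p)


RMOUT_HEADER = "   SW  perc perc perc  query\n score  div. del. ins.  sequence\n\n"


class TestRepeats:
    def test_rmout_coordinate_conversion(self, tmp_path):
        p = tmp_path / "x.out"
        p.write_text(RMOUT_HEADER +
                     " 1000 10.0 0.0 0.0 s1 101 200 (0) + rep LINE/L2 1 100 (0) 1\n")
        ann = fio.read_repeat_annotation(p, "rmout")
        (row,) = ann.intervals
        assert row[:3] == ("s1", 100, 200)
        assert row[4] == "LINE"

    @pytest.mark.parametrize("raw, class8", [
        ("Unknown", "unknown"),
        ("Satellite", "other"),
        ("SINE/tRNA", "SINE"),
        ("DNA/hAT-Charlie", "DNA"),
        ("RC/Helitron", "DNA"),
        ("LTR/Gypsy", "LTR"),
        ("Simple_repeat", "simple"),
        ("Low_complexity", "low_complexity"),
        ("rRNA", "other"),
    ])
    def test_class_collapse(self, raw, class8):
        assert fio.collapse_repeat_class(raw) == class8

    def test_rmout_total_bases_match_bruteforce(self, tmp_path, rng):
        rows, expected = [], 0
        for i in range(50):
            begin = int(rng.integers(1, 5000))
            end = begin + int(rng.integers(1, 500))
            expected += end - begin + 1
            rows.append(f" 1 1.0 0.0 0.0 s1 {begin} {end} (0) + rep Unknown 1 1 (0) {i}\n")
        p = tmp_path / "x.out"
        p.write_text(RMOUT_HEADER + "".join(rows))
        ann = fio.read_repeat_annotation(p, "rmout")
        assert ann.total_bases() == expected

    def test_bed_round_trip_is_identity(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("s1\t100\t200\tLINE/L2\n")
        ann = fio.read_repeat_annotation(p, "bed")
        out = tmp_path / "y.bed"
        fio.write_repeat_bed(ann, out)
        again = fio.read_repeat_annotation(out, "bed")
        assert ann.intervals[0][:3] == again.intervals[0][:3]

    def test_unknown_dialect_rejected(self, tmp_path):
        p = tmp_path / "x.gff"
        p.write_text("")
        with pytest.raises(ValueError, match="dialect"):
            fio.read_repeat_annotation(p, "gff")

    def test_degenerate_interval_rejected(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("s1\t200\t200\tLINE\n")
        with pytest.raises(fio.FormatError, match="start >= end"):
            fio.read_repeat_annotation(p, "bed")


class TestTables:
    def test_fai_round_trip(self, tmp_path, scaffolds):
        p = tmp_path / "x.fai"
        fio.write_fai(scaffolds, p)
        back = fio.read_fai(p, assembly_id="asm")
        assert back.names == scaffolds.names
        assert back.length("s2") == 2000

    def test_depth_bed_round_trip(self, tmp_path):
        import pandas as pd

        t = fio.DepthWindowTable(pd.DataFrame(
            {"scaffold": ["s1", "s1"], "start": [0, 1000],
             "end": [1000, 2000], "depth": [30.0, 15.5]}), 1000)
        p = tmp_path / "d.bed"
        fio.write_depth_bed(t, p)
        back = fio.read_depth_bed(p)
        assert back.window_size == 1000
        assert list(back.table["depth"]) == [30.0, 15.5]

    def test_qpcr_reader(self, tmp_path):
        p = tmp_path / "cq.tsv"
        p.write_text("assay\tcq\nA\t20.0\nA\t20.1\nS\t19.2\nS\t19.1\n")
        a, s = fio.read_qpcr_table(p)
        assert len(a) == 2 and len(s) == 2
        assert a.mean() == pytest.approx(20.05)


class TestAlignments:
    @pytest.mark.parametrize("cigar, span", [
        ("100M", 100), ("50M10I50M", 100), ("50M10D50M", 110),
        ("10S100M5S", 100), ("100=", 100), ("*", 0),
    ])
    def test_cigar_reference_length(self, cigar, span):
        assert fio.cigar_reference_length(cigar) == span

    def test_alignment_tsv(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("q1\ts1\t100\t60\t100M\t0\t0\nq1\ts2\t0\t60\t50M\t1\t0\n")
        recs = fio.read_alignment_tsv(p)
        assert recs[1].is_supplementary and not recs[0].is_supplementary

    def test_sam_text(self, tmp_path):
        p = tmp_path / "a.sam"
        p.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:s1\tLN:1000\n"
            "q1\t0\ts1\t101\t60\t100M\t*\t0\t0\t*\t*\n"
            "q2\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n")
        recs = fio.read_sam_alignments(p)
        assert len(recs) == 1
        assert recs[0].target_start == 100  # SAM is 1-based
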