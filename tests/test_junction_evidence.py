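import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from karyocourt import junction_evidence as jev
from karyocourt.breakpoint_stats import BreakpointSpec
from karyocourt.formats_io import AlignmentRecord, RepeatAnnotation, ScaffoldSet


@pytest.fixture
def scaffolds():
    return ScaffoldSet("asm", [("L", 400_000), ("R", 300_000)])


def aln(query, target, start, mapq=60, cigar="1000M", supp=False, dup=False):
    return AlignmentRecord(query, target, start, mapq, cigar, supp, dup)


class TestTerminalWindowDepth:
    def test_single_read_fills_one_bin(self, scaffolds):
        t = jev.terminal_window_depth([aln("q", "L", 0)], scaffolds, "L", "start")
        assert t.bins[0] == pytest.approx(1.0)
        assert t.bins[1:].sum() == 0

    def test_low_mapq_contributes_nothing(self, scaffolds):
        t = jev.terminal_window_depth([aln("q", "L", 0, mapq=5)], scaffolds, "L", "start")
        assert t.bins.sum() == 0

    def test_duplicates_excluded(self, scaffolds):
        t = jev.terminal_window_depth([aln("q", "L", 0, dup=True)], scaffolds, "L", "start")
        assert t.bins.sum() == 0

    def test_end_terminus_window_placement(self, scaffolds):
        # read covering the last 1 kb of L (400 kb long)
        t = jev.terminal_window_depth([aln("q", "L", 399_000)], scaffolds, "L", "end")
        assert t.window_start == 200_000
        assert t.bins[-1] == pytest.approx(1.0)

    def test_matches_per_base_pileup_oracle(self, scaffolds, rng):
        alignments = [
            aln(f"q{i}", "L", int(rng.integers(0, 195_000)),
                cigar=f"{int(rng.integers(100, 5000))}M",
                mapq=int(rng.integers(0, 61)))
            for i in range(300)
        ]
        t = jev.terminal_window_depth(alignments, scaffolds, "L", "start",
                                      window=200_000)
        per_base = np.zeros(200_000)
        for a in alignments:
            if a.mapq >= 10:
                span = int(a.cigar[:-1])
                per_base[a.target_start:a.target_start + span] += 1
        expected = per_base.reshape(200, 1000).mean(axis=1)
        np.testing.assert_allclose(t.bins, expected)


class TestSpanningReads:
    @pytest.fixture
    def bp(self):
        return BreakpointSpec("BP1", "asm", "L", "R", "other", "X", 400_000,
                              orientation=("end", "start"))

    def test_split_alignment_counted_once(self, scaffolds, bp):
        alignments = [
            aln("q1", "L", 397_000, cigar="2000M"),           # ends 1 kb from L's end
            aln("q1", "R", 3_000, cigar="2000M", supp=True),  # 3 kb into R
        ]
        assert jev.detect_spanning_reads(alignments, bp, scaffolds) == 1

    def test_both_alignments_on_one_side_not_counted(self, scaffolds, bp):
        alignments = [
            aln("q1", "L", 397_000, cigar="2000M"),
            aln("q1", "L", 380_000, cigar="2000M", supp=True),
        ]
        assert jev.detect_spanning_reads(alignments, bp, scaffolds) == 0

    def test_far_from_terminus_not_counted(self, scaffolds, bp):
        alignments = [
            aln("q1", "L", 100_000, cigar="2000M"),
            aln("q1", "R", 3_000, cigar="2000M", supp=True),
        ]
        assert jev.detect_spanning_reads(alignments, bp, scaffolds) == 0

    def test_unassembled_junction_simulation_has_no_spanning_reads(self, scaffolds, bp):
        # reads never produced across the junction: any random same-side pile
        alignments = [aln(f"q{i}", "L", 1000 * i, cigar="500M") for i in range(50)]
        assert jev.detect_spanning_reads(alignments, bp, scaffolds) == 0


class TestCoverageFold:
    def test_ratio_definition(self):
        track = np.r_[np.full(175, 25.0), np.full(50, 5.0), np.full(175, 25.0)]
        res = jev.coverage_fold(track, junction_exclude=0)
        assert res.fold == pytest.approx(5.0)
        assert res.low_mappability

    def test_uniform_depth_is_unity(self):
        res = jev.coverage_fold(np.full(400, 30.0))
        assert res.fold == pytest.approx(1.0)
        assert not res.low_mappability

    def test_zero_core_flags_infinite(self):
        track = np.r_[np.full(175, 25.0), np.zeros(50), np.full(175, 25.0)]
        res = jev.coverage_fold(track, junction_exclude=0)
        assert res.infinite and res.low_mappability

    @given(st.floats(0.1, 100.0))
    def test_scale_invariance(self, c):
        track = np.r_[np.full(150, 20.0), np.full(100, 4.0), np.full(150, 20.0)]
        base = jev.coverage_fold(track).fold
        scaled = jev.coverage_fold(track * c).fold
        assert scaled == pytest.approx(base)

    def test_core_must_fit_in_track(self):
        with pytest.raises(ValueError, match="core"):
            jev.coverage_fold(np.ones(10), core=50_000)


def ann(rows):
    return RepeatAnnotation(pd.DataFrame(
        rows, columns=["scaffold", "start", "end", "raw_class", "class8"]))


class TestMaskedFraction:
    def test_interval_arithmetic(self):
        a = ann([("s", 0, 100, "LINE/L2", "LINE"), ("s", 50, 150, "LTR/Gypsy", "LTR")])
        prof = jev.window_masked_fraction(a, ("s", 0, 200))
        assert prof.class_fractions["LINE"] == pytest.approx(0.5)
        assert prof.class_fractions["LTR"] == pytest.approx(0.5)
        assert prof.total_fraction == pytest.approx(0.75)

    def test_within_class_overlap_merged(self):
        a = ann([("s", 0, 100, "LINE/L2", "LINE"), ("s", 50, 150, "LINE/L1", "LINE")])
        prof = jev.window_masked_fraction(a, ("s", 0, 200))
        assert prof.class_fractions["LINE"] == pytest.approx(0.75)

    def test_matches_per_base_oracle(self, rng):
        classes = ["LINE", "DNA", "unknown"]
        rows = []
        for _ in range(80):
            s = int(rng.integers(0, 9_500))
            e = s + int(rng.integers(1, 800))
            c = classes[rng.integers(0, 3)]
            rows.append(("s", s, e, c, c))
        a = ann(rows)
        prof = jev.window_masked_fraction(a, ("s", 1000, 9000))
        span = 8000
        marks = {c: np.zeros(span, dtype=bool) for c in classes}
        union = np.zeros(span, dtype=bool)
        for _, s, e, _, c in rows:
            s2, e2 = max(s, 1000) - 1000, min(e, 9000) - 1000
            if e2 > s2:
                marks[c][s2:e2] = True
                union[s2:e2] = True
        for c in classes:
            assert prof.class_fractions[c] == pytest.approx(marks[c].mean())
        assert prof.total_fraction == pytest.approx(union.mean())

    def test_fraction_bounds_invariant(self, rng):
        rows = []
        for _ in range(40):
            s = int(rng.integers(0, 5000))
            rows.append(("s", s, s + int(rng.integers(1, 3000)), "Unknown", "unknown"))
        prof = jev.window_masked_fraction(ann(rows), ("s", 0, 5000))
        fs = prof.class_fractions
        assert 0.0 <= prof.total_fraction <= 1.0
        assert max(fs.values()) <= prof.total_fraction <= min(1.0, sum(fs.values()))

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            jev.window_masked_fraction(ann([]), ("s", 100, 100))


class TestRepeatComparison:
    def prof(self, total, unknown=0.0, wid="w"):
        return jev.RepeatWindowProfile(wid, "s", 0, 1000, {"unknown": unknown}, total)

    def test_means_and_enrichment(self):
        cmp = jev.compare_junction_repeats(
            [self.prof(0.72), self.prof(0.71)],
            [self.prof(0.68), self.prof(0.67)])
        assert cmp.junction_mean_total == pytest.approx(0.715)
        assert cmp.control_mean_total == pytest.approx(0.675)
        assert cmp.repeat_enriched

    def test_identical_profiles_not_enriched(self):
        cmp = jev.compare_junction_repeats([self.prof(0.5)], [self.prof(0.5)])
        assert cmp.diff_total == pytest.approx(0.0)
        assert not cmp.repeat_enriched

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            jev.compare_junction_repeats([], [self.prof(0.5)])
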