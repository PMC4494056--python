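from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsreg.core_genomics import (
    AlignmentChain,
    BedParseError,
    BindingSite,
    ChainFormatError,
    GenomicInterval,
    IntervalSet,
    intersect,
    read_bed,
    read_chain,
    read_repeatmasker,
    window_around_midpoint,
    write_bed,
    write_chain,
)


# ---------------------------------------------------------------------------
# GenomicInterval / IntervalSet

class TestGenomicInterval:
    def test_basic_fields(self):
        iv = GenomicInterval("chr1", 0, 200)
        assert iv.length() == 200
        assert iv.midpoint == 100

    @pytest.mark.parametrize("start,end", [(5, 5), (10, 3), (-1, 10)])
    def test_invalid_intervals_rejected(self, start, end):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", start, end)

    def test_half_open_abutment_has_zero_overlap(self):
        # convention check: [a,b) and [b,c) are disjoint
        a = GenomicInterval("chr1", 0, 200)
        b = GenomicInterval("chr1", 200, 300)
        assert a.overlap(b) == 0

    def test_contains_point_half_open(self):
        iv = GenomicInterval("chr1", 10, 20)
        assert iv.contains_point("chr1", 10)
        assert iv.contains_point("chr1", 19)
        assert not iv.contains_point("chr1", 20)


class TestIntervalSet:
    def test_duplicates_kept_coverage_merged(self):
        ivs = IntervalSet([GenomicInterval("chr1", 0, 100)] * 3)
        assert len(ivs) == 3
        assert ivs.coverage() == 100

    def test_order_independence(self):
        a = IntervalSet([GenomicInterval("chr1", 50, 150),
                         GenomicInterval("chr1", 0, 100)])
        b = IntervalSet([GenomicInterval("chr1", 0, 100),
                         GenomicInterval("chr1", 50, 150)])
        assert list(a) == list(b)
        assert a.coverage() == b.coverage() == 150

    def test_genome_fraction(self):
        ivs = IntervalSet([GenomicInterval("chr1", 0, 429)],
                          genome_size={"chr1": 1000})
        assert ivs.genome_fraction() == pytest.approx(0.429)


# ---------------------------------------------------------------------------
# BED I/O

class TestReadBed:
    def test_single_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t200\n")
        ivs = read_bed(str(p))
        assert list(ivs) == [GenomicInterval("chr1", 0, 200)]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert len(read_bed(str(p))) == 0

    def test_duplicates_kept_vs_hand_parse(self, tmp_path):
        p = tmp_path / "dup.bed"
        p.write_text("chr1\t0\t100\nchr1\t0\t100\nchr2\t5\t50\n")
        ivs = read_bed(str(p))
        # hand parse: 3 lines, one duplicated -> 3 intervals retained
        assert len(ivs) == 3

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t100\nchr1\tnope\t5\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bed(str(p))

    def test_end_le_start_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t100\n")
        with pytest.raises(BedParseError):
            read_bed(str(p))

    def test_roundtrip_six_column(self, tmp_path):
        content = "chr1\t0\t100\tsiteA\t0\t+\nchr2\t5\t50\tsiteB\t0\t-\n"
        p = tmp_path / "rt.bed"
        p.write_text(content)
        out = tmp_path / "out.bed"
        write_bed(str(out), read_bed(str(p)))
        assert out.read_text() == content


# ---------------------------------------------------------------------------
# Chain parsing

def _chain_text(header: str, body: str) -> str:
    return header + "\n" + body + "\n"


class TestReadChain:
    def test_single_block(self, tmp_path):
        p = tmp_path / "a.chain"
        p.write_text(_chain_text(
            "chain 100 chr1 1000 + 0 100 chr1 1000 + 0 100 1", "100"))
        (chain,) = read_chain(str(p))
        assert chain.target_blocks() == [(0, 100)]
        assert chain.subject_span == GenomicInterval("chr1", 0, 100)

    def test_two_block_hand_arithmetic(self, tmp_path):
        # blocks (50, dt=10, dq=0), (40): target span 100, subject span 90
        p = tmp_path / "b.chain"
        p.write_text(_chain_text(
            "chain 90 chr1 1000 + 0 100 chr1 1000 + 0 90 1", "50 10 0\n40"))
        (chain,) = read_chain(str(p))
        assert chain.t_end - chain.t_start == 100
        assert chain.q_end - chain.q_start == 90
        assert chain.target_blocks() == [(0, 50), (60, 100)]

    def test_negative_strand_normalized(self, tmp_path):
        # q on '-' over strand-local [0, 100) of a 1000-bp chrom: forward
        # coordinates are [900, 1000)
        p = tmp_path / "c.chain"
        p.write_text(_chain_text(
            "chain 100 chr1 1000 + 0 100 chrQ 1000 - 0 100 7", "100"))
        (chain,) = read_chain(str(p))
        assert chain.subject_span == GenomicInterval("chrQ", 900, 1000)
        # manual reverse mapping round-trip: target [0,10) -> last 10 forward bases
        mapped = chain.map_interval(GenomicInterval("chr1", 0, 10))
        assert (mapped.start, mapped.end) == (990, 1000)

    def test_arithmetic_mismatch_rejected(self, tmp_path):
        p = tmp_path / "bad.chain"
        p.write_text(_chain_text(
            "chain 90 chr1 1000 + 0 100 chr1 1000 + 0 90 1", "50 10 0\n41"))
        with pytest.raises(ChainFormatError):
            read_chain(str(p))

    def test_truncated_chain_rejected(self, tmp_path):
        p = tmp_path / "trunc.chain"
        p.write_text("chain 90 chr1 1000 + 0 100 chr1 1000 + 0 90 1\n50 10 0\n")
        with pytest.raises(ChainFormatError):
            read_chain(str(p))

    def test_write_read_roundtrip(self, tmp_path):
        chain = AlignmentChain(1, 90.0, "chr1", 1000, "+", 0, 100,
                               "chr2", 500, "+", 10, 100, [(50, 10, 0), (40, 0, 0)])
        p = tmp_path / "rt.chain"
        write_chain(str(p), [chain])
        (back,) = read_chain(str(p))
        assert back.blocks == chain.blocks
        assert back.t_name == "chr1" and back.q_name == "chr2"


# ---------------------------------------------------------------------------
# RepeatMasker

_RM_HEADER = (
    "   SW  perc perc perc  query     position in query    matching repeat\n"
    "score  div. del. ins.  sequence  begin  end   (left)  repeat   class/family\n"
    "\n"
)


class TestReadRepeatmasker:
    def test_out_coordinates_converted(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(_RM_HEADER +
                     "  500  0.5 0.0 0.0 chr1 1 6000 (994000) + L1HS LINE/L1 1 6000 (0) 1\n")
        (ann,) = read_repeatmasker(str(p), "out")
        assert (ann.interval.start, ann.interval.end) == (0, 6000)
        assert ann.divergence_pct == 0.5
        assert ann.repeat_class == "LINE"

    def test_bed_dialect_no_divergence(self, tmp_path):
        p = tmp_path / "rm.bed"
        p.write_text("chr1\t0\t450\tLTR7\t0\t+\tLTR\n")
        (ann,) = read_repeatmasker(str(p), "bed")
        assert ann.divergence_pct is None
        assert ann.repeat_name == "LTR7" and ann.repeat_class == "LTR"

    def test_family_counts_hand_tally(self, tmp_path):
        p = tmp_path / "rm.out"
        rows = [
            "  500  0.5 0.0 0.0 chr1 1 6000 (0) + L1HS LINE/L1 1 6000 (0) 1\n",
            "  500  0.7 0.0 0.0 chr1 10000 16000 (0) C L1HS LINE/L1 (0) 6000 1 2\n",
            "  300  1.0 0.0 0.0 chr2 1 450 (0) + LTR7 LTR/ERV1 1 450 (0) 3\n",
        ]
        p.write_text(_RM_HEADER + "".join(rows))
        anns = read_repeatmasker(str(p), "out")
        counts = {}
        for a in anns:
            counts[a.repeat_name] = counts.get(a.repeat_name, 0) + 1
        assert counts == {"L1HS": 2, "LTR7": 1}

    def test_unknown_dialect(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text("")
        with pytest.raises(ValueError):
            read_repeatmasker(str(p), "gff")


# ---------------------------------------------------------------------------
# intersect

def _naive_all_pairs(a, b, min_overlap):
    out = []
    for ia in a:
        for ib in b:
            if ia.chrom != ib.chrom:
                continue
            ov = min(ia.end, ib.end) - max(ia.start, ib.start)
            if ov >= min_overlap:
                out.append((ia, ib, ov))
    return sorted(out, key=lambda t: (t[0].chrom, t[0].start, t[0].end,
                                      t[1].start, t[1].end))


class TestIntersect:
    def test_basic_pair(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 200)])
        b = IntervalSet([GenomicInterval("chr1", 100, 300)])
        ((ia, ib, ov),) = intersect(a, b, 1)
        assert ov == 100

    def test_abutment_no_pair(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 200)])
        b = IntervalSet([GenomicInterval("chr1", 200, 300)])
        assert intersect(a, b, 1) == []

    def test_empty_inputs(self):
        assert intersect(IntervalSet(), IntervalSet(), 1) == []

    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_matches_naive_oracle(self, data):
        def rand_set(n):
            ivs = []
            for _ in range(n):
                chrom = data.draw(st.sampled_from(["chr1", "chr2"]))
                start = data.draw(st.integers(0, 900))
                length = data.draw(st.integers(1, 120))
                ivs.append(GenomicInterval(chrom, start, start + length))
            return ivs

        a_list = rand_set(data.draw(st.integers(0, 60)))
        b_list = rand_set(data.draw(st.integers(0, 60)))
        min_ov = data.draw(st.integers(1, 30))
        got = intersect(IntervalSet(a_list), IntervalSet(b_list), min_ov)
        assert got == _naive_all_pairs(a_list, b_list, min_ov)

    def test_symmetry(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 50),
                         GenomicInterval("chr1", 40, 90)])
        b = IntervalSet([GenomicInterval("chr1", 30, 60)])
        ab = {(x.start, y.start, o) for x, y, o in intersect(a, b)}
        ba = {(y.start, x.start, o) for x, y, o in intersect(b, a)}
        assert ab == ba


# ---------------------------------------------------------------------------
# window_around_midpoint / BindingSite

class TestWindowAroundMidpoint:
    def test_point_peak(self):
        w = window_around_midpoint(GenomicInterval("chr1", 1000, 1001), 200)
        assert (w.start, w.end) == (900, 1100)

    def test_left_clip_shift(self):
        w = window_around_midpoint(GenomicInterval("chr1", 0, 1), 200)
        assert (w.start, w.end) == (0, 200)

    def test_odd_length_peak_hand_arithmetic(self):
        # peak [100, 301): midpoint floor(401/2) = 200, window [100, 300)
        w = window_around_midpoint(GenomicInterval("chr1", 100, 301), 200)
        assert (w.start, w.end) == (100, 300)

    def test_chromosome_shorter_than_window(self):
        with pytest.raises(ValueError):
            window_around_midpoint(GenomicInterval("chr1", 10, 20), 200,
                                   chrom_size=150)

    def test_binding_site_window_width(self):
        site = BindingSite("NANOG", GenomicInterval("chr1", 500, 700))
        assert site.window.length() == 200
        assert site.peak.start <= site.midpoint < site.peak.end
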