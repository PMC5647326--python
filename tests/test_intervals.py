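"""Interval model, readers, promoter construction, and the de-overlap rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tfcobind import (
    GenomicInterval,
    TssRecord,
    gap_distance,
    make_promoters,
    overlaps,
    read_bed,
    read_tss_table,
    remove_overlapping_keep_shortest,
    write_bed6,
)
from tfcobind.intervals import RegionSet, has_overlaps

from conftest import make_regions, random_regions


def intervals_strategy(max_coord=1000):
    return st.builds(
        lambda c, s, l: GenomicInterval(c, s, s + l),
        st.sampled_from(["chr1", "chr2"]),
        st.integers(0, max_coord),
        st.integers(1, 200),
    )


class TestGenomicInterval:
    def test_rejects_inverted_and_negative_coordinates(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -5, 100)

    def test_length_and_midpoint(self):
        iv = GenomicInterval("chr1", 100, 200)
        assert iv.length == 100
        assert iv.midpoint == 150


class TestOverlapsAndGap:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (("chr1", 0, 100), ("chr1", 100, 200), False),  # half-open abutment
            (("chr1", 0, 100), ("chr1", 99, 200), True),    # 1-bp intersection
            (("chr1", 0, 100), ("chr2", 0, 100), False),    # different chromosome
            (("chr1", 10, 20), ("chr1", 0, 100), True),     # containment
        ],
    )
    def test_overlap_examples(self, a, b, expected):
        assert overlaps(GenomicInterval(*a), GenomicInterval(*b)) is expected

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (("chr1", 100, 200), ("chr1", 150, 250), 0),      # overlap
            (("chr1", 100, 200), ("chr1", 1200, 1300), 1000), # 1200 - 200
            (("chr1", 100, 200), ("chr3", 100, 200), None),   # unreachable
            (("chr1", 0, 100), ("chr1", 100, 200), 0),        # abutment
        ],
    )
    def test_gap_examples(self, a, b, expected):
        assert gap_distance(GenomicInterval(*a), GenomicInterval(*b)) == expected

    @settings(max_examples=200, derandomize=True)
    @given(intervals_strategy(), intervals_strategy())
    def test_overlap_symmetric_and_gap_consistent(self, a, b):
        assert overlaps(a, b) == overlaps(b, a)
        if a.chrom == b.chrom:
            assert (gap_distance(a, b) == 0 and gap_distance(a, b) is not None) == (
                overlaps(a, b) or max(a.start, b.start) == min(a.end, b.end)
            )
            assert gap_distance(a, b) == gap_distance(b, a)
        else:
            assert gap_distance(a, b) is None


class TestBedReader:
    def test_three_records_two_chromosomes(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\nchr1\t300\t400\nchr2\t0\t50\n")
        rs = read_bed(p)
        assert len(rs) == 3
        assert len(rs.by_chrom("chr1")) == 2
        assert len(rs.by_chrom("chr2")) == 1
        assert rs.by_chrom("chr1")[0] == GenomicInterval("chr1", 100, 200)

    def test_inverted_record_names_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t200\t100\n")
        with pytest.raises(ValueError, match="line 1"):
            read_bed(p)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t200\nchr1\t500\n")
        with pytest.raises(ValueError, match="line 2"):
            read_bed(p)

    def test_narrowpeak_requires_ten_fields_and_reads_name(self, tmp_path):
        p = tmp_path / "p.narrowPeak"
        p.write_text("chr1\t10\t60\tpk1\t800\t.\t5.1\t12.0\t10.1\t25\n")
        rs = read_bed(p, format="narrowPeak")
        assert list(rs)[0].label == "pk1"
        p2 = tmp_path / "short.narrowPeak"
        p2.write_text("chr1\t10\t60\n")
        with pytest.raises(ValueError, match="line 1"):
            read_bed(p2, format="narrowPeak")

    def test_skips_comments_and_roundtrips_bed6(self, tmp_path):
        p = tmp_path / "c.bed"
        p.write_text("# comment\ntrack name=x\nchrU_random\t5\t15\tpk\t0\t-\n")
        rs = read_bed(p)
        assert len(rs) == 1  # unplaced contigs retained
        out = tmp_path / "out.bed"
        write_bed6(rs, out)
        back = read_bed(out)
        assert list(back)[0] == GenomicInterval("chrU_random", 5, 15, strand="-", label="pk")


class TestPromoters:
    def test_plus_strand_clipped_at_zero(self):
        rs = make_promoters([TssRecord("gA", "chr1", 1000, "+")], upstream=2000, downstream=500)
        assert list(rs)[0] == GenomicInterval("chr1", 0, 1500, strand="+", label="gA")

    def test_minus_strand_mirrors_plus(self):
        rs = make_promoters([TssRecord("gA", "chr1", 1000, "-")], upstream=2000, downstream=500)
        assert list(rs)[0] == GenomicInterval("chr1", 500, 3000, strand="-", label="gA")

    def test_minimal_window(self):
        rs = make_promoters([TssRecord("gA", "chr1", 5000, "+")], upstream=0, downstream=1)
        iv = list(rs)[0]
        assert (iv.start, iv.end) == (5000, 5001)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            make_promoters([TssRecord("gA", "chr1", 5000, "+")], upstream=0, downstream=0)

    def test_unknown_strand_names_gene(self):
        with pytest.raises(ValueError, match="gX"):
            TssRecord("gX", "chr1", 100, ".")

    @settings(max_examples=50, derandomize=True)
    @given(st.integers(3000, 50_000), st.sampled_from(["+", "-"]),
           st.integers(0, 2000), st.integers(0, 500))
    def test_mirror_reflection(self, tss, strand, up, down):
        """Reflecting TSS coordinates and flipping strand reflects the promoter."""
        if up + down == 0:
            up = 1
        axis = 100_000
        flipped = "-" if strand == "+" else "+"
        orig = list(make_promoters([TssRecord("g", "chr1", tss, strand)], up, down))[0]
        mirr = list(make_promoters([TssRecord("g", "chr1", axis - tss, flipped)], up, down))[0]
        assert (mirr.start, mirr.end) == (axis - orig.end, axis - orig.start)

    def test_tss_table_roundtrip(self, tmp_path):
        p = tmp_path / "tss.tsv"
        p.write_text("gene\tchrom\ttss\tstrand\ngA\tchr1\t1000\t+\ngB\tchr2\t500\t-\n")
        recs = read_tss_table(p)
        assert recs == [TssRecord("gA", "chr1", 1000, "+"), TssRecord("gB", "chr2", 500, "-")]


def greedy_discard_oracle(intervals):
    """Literal O(n^2) restatement of the rule: while any overlap exists,
    discard the longest involved interval (tie: larger start)."""
    alive = list(intervals)
    while True:
        involved = set()
        for i, a in enumerate(alive):
            for j, b in enumerate(alive):
                if i < j and overlaps(a, b):
                    involved.add(i)
                    involved.add(j)
        if not involved:
            return alive
        victim = max(involved, key=lambda i: (alive[i].length, alive[i].start))
        del alive[victim]


class TestDeoverlap:
    def test_keeps_contained_shorter(self):
        rs = make_regions("d", [("chr1", 0, 100), ("chr1", 50, 80)])
        out = remove_overlapping_keep_shortest(rs)
        assert [(iv.start, iv.end) for iv in out] == [(50, 80)]

    def test_disjoint_unchanged(self):
        rs = make_regions("d", [("chr1", 0, 100), ("chr1", 200, 300)])
        assert len(remove_overlapping_keep_shortest(rs)) == 2

    def test_equal_length_tie_keeps_leftmost(self):
        rs = make_regions("d", [("chr1", 0, 50), ("chr1", 40, 90)])
        out = remove_overlapping_keep_shortest(rs)
        assert [(iv.start, iv.end) for iv in out] == [(0, 50)]

    def test_chain_discards_longest_repeatedly(self):
        # A(0,10), B(5,15), C(12,30): C longest involved goes first, then the
        # A/B tie resolves to keeping A. ("Keep shortest first" would keep C.)
        rs = make_regions("d", [("chr1", 0, 10), ("chr1", 5, 15), ("chr1", 12, 30)])
        out = remove_overlapping_keep_shortest(rs)
        assert [(iv.start, iv.end) for iv in out] == [(0, 10)]

    def test_matches_oracle_and_idempotent_on_random_sets(self):
        rng = np.random.default_rng(42)
        for trial in range(30):
            rs = random_regions(rng, int(rng.integers(2, 40)), span=2000, max_len=400)
            out = remove_overlapping_keep_shortest(rs)
            assert not has_overlaps(out)
            expected = greedy_discard_oracle(list(rs))
            assert sorted((iv.chrom, iv.start, iv.end) for iv in out) == sorted(
                (iv.chrom, iv.start, iv.end) for iv in expected
            )
            twice = remove_overlapping_keep_shortest(out)
            assert sorted((iv.chrom, iv.start, iv.end) for iv in twice) == sorted(
                (iv.chrom, iv.start, iv.end) for iv in out
            )


class TestRegionSetIndex:
    def test_query_agrees_with_all_pairs_scan(self):
        rng = np.random.default_rng(7)
        targets = random_regions(rng, 200, name="t")
        queries = random_regions(rng, 100, name="q")
        for q in queries:
            hits = {iv.key for iv in targets.overlapping(q)}
            brute = {iv.key for iv in targets if overlaps(q, iv)}
            assert hits == brute

    def test_point_query_half_open(self):
        rs = make_regions("d", [("chr1", 0, 1000)])
        assert rs.at_point("chr1", 999)
        assert not rs.at_point("chr1", 1000)
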