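"""Interval/coverage algebra and the strict BED/bedGraph dialects."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crest.genome import (
    CoverageTrack,
    GeneAnnotation,
    GenomeModel,
    GenomicInterval,
    IntervalSet,
    intersect_bases,
    merge_intervals,
    nearest_tss,
    overlapping_subset,
    signal_in_interval,
    subtract_intervals,
    union_bases,
)
from crest.io import ParseError, read_bed, read_bedgraph, write_bed, write_bedgraph

from conftest import (
    bases_of,
    oracle_intersect,
    oracle_merge,
    oracle_overlapping_subset,
    oracle_signal,
    oracle_union,
    random_interval_set,
)


def iset(*triples, genome=None):
    return IntervalSet([GenomicInterval(*t) for t in triples], genome)


class TestGenomeModel:
    def test_rejects_bad_lengths(self):
        with pytest.raises(ValueError):
            GenomeModel({"chr1": 0})
        with pytest.raises(ValueError):
            GenomeModel({})

    def test_interval_outside_chromosome_rejected(self, toy_genome):
        with pytest.raises(ValueError, match="exceeds"):
            iset(("chr1", 0, 20_000), genome=toy_genome)
        with pytest.raises(ValueError, match="unknown"):
            iset(("chrX", 0, 10), genome=toy_genome)


class TestBedIO:
    def test_single_line_maps_fields(self, tmp_path, toy_genome):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\tpkA\n")
        s = read_bed(p, toy_genome)
        assert [(iv.chrom, iv.start, iv.end, iv.name) for iv in s] == [("chr1", 0, 100, "pkA")]

    def test_empty_file_gives_empty_set(self, tmp_path, toy_genome):
        p = tmp_path / "e.bed"
        p.write_text("")
        assert len(read_bed(p, toy_genome)) == 0

    @pytest.mark.parametrize(
        "line",
        ["chr1\t100\t100", "chr1\tx\t200", "chr1\t300\t200", "chrZ\t0\t10"],
        ids=["zero-length", "non-integer", "inverted", "unknown-chrom"],
    )
    def test_malformed_lines_raise_with_line_number(self, tmp_path, toy_genome, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t50\n" + line + "\n")
        with pytest.raises(ParseError, match=":2"):
            read_bed(p, toy_genome)

    def test_round_trip_preserves_names_and_scores(self, tmp_path, toy_genome):
        original = IntervalSet(
            [
                GenomicInterval("chr1", 5, 107, "a", 1.25),
                GenomicInterval("chr2", 0, 999, "b", -3.5),
                GenomicInterval("chr1", 200, 300, "c", 0.1),
            ],
            toy_genome,
        )
        p = tmp_path / "rt.bed"
        write_bed(original, p)
        assert read_bed(p, toy_genome).intervals == original.intervals

    def test_three_column_output_for_bare_intervals(self, tmp_path, toy_genome):
        p = tmp_path / "bare.bed"
        write_bed(iset(("chr1", 0, 10)), p)
        assert p.read_text() == "chr1\t0\t10\n"


class TestBedGraphIO:
    def test_total_signal(self, tmp_path, toy_genome):
        p = tmp_path / "t.bdg"
        p.write_text("chr1\t0\t10\t2.0\n")
        assert read_bedgraph(p, toy_genome).total_signal() == 20.0

    def test_abutting_steps_sum(self, tmp_path, toy_genome):
        p = tmp_path / "t.bdg"
        p.write_text("chr1\t0\t5\t1\nchr1\t5\t10\t3\n")
        assert read_bedgraph(p, toy_genome).total_signal() == 20.0

    def test_overlap_and_negative_are_errors(self, tmp_path, toy_genome):
        p = tmp_path / "o.bdg"
        p.write_text("chr1\t0\t10\t1\nchr1\t5\t15\t1\n")
        with pytest.raises(ParseError, match="overlap"):
            read_bedgraph(p, toy_genome)
        p.write_text("chr1\t0\t10\t-1\n")
        with pytest.raises(ParseError, match="negative"):
            read_bedgraph(p, toy_genome)

    def test_round_trip_lossless(self, tmp_path, toy_genome):
        track = CoverageTrack(
            [("chr1", 0, 7, 0.30000000000000004), ("chr1", 9, 20, 5.1), ("chr2", 3, 4, 1e-9)]
        )
        p = tmp_path / "rt.bdg"
        write_bedgraph(track, p)
        back = read_bedgraph(p, toy_genome)
        assert list(back.steps()) == list(track.steps())


class TestMerge:
    def test_abutting_merge(self):
        merged = merge_intervals(iset(("chr1", 0, 10), ("chr1", 10, 20)))
        assert [(iv.start, iv.end) for iv in merged] == [(0, 20)]

    def test_separated_stay_apart_at_gap_zero(self):
        merged = merge_intervals(iset(("chr1", 0, 10), ("chr1", 15, 20)))
        assert [(iv.start, iv.end) for iv in merged] == [(0, 10), (15, 20)]

    def test_min_gap_five_closes_five_base_gap(self, toy_genome):
        s = iset(("chr1", 0, 10), ("chr1", 15, 20), genome=toy_genome)
        merged = merge_intervals(s, min_gap=5)
        assert [(iv.start, iv.end) for iv in merged] == [(0, 20)]
        expected = oracle_merge(s, toy_genome, min_gap=5)
        assert merged.intervals == expected.intervals


class TestBaseCounts:
    def test_identical_and_disjoint(self):
        a = iset(("chr1", 0, 100))
        assert intersect_bases(a, a) == 100
        assert union_bases(a, a) == 100
        b = iset(("chr1", 200, 300))
        assert intersect_bases(a, b) == 0
        assert union_bases(a, b) == 200

    def test_partial_overlap_matches_oracle(self, toy_genome):
        a = iset(("chr1", 0, 100), genome=toy_genome)
        b = iset(("chr1", 50, 150), genome=toy_genome)
        assert intersect_bases(a, b) == 50 == oracle_intersect(a, b, toy_genome)
        assert union_bases(a, b) == 150 == oracle_union(a, b, toy_genome)

    def test_half_open_intervals_never_intersect_at_boundary(self):
        assert intersect_bases(iset(("chr1", 0, 10)), iset(("chr1", 10, 20))) == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_and_fragmentation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        genome = GenomeModel({"chr1": 500, "chr2": 300})
        a = random_interval_set(rng, genome, 10)
        b = random_interval_set(rng, genome, 10)
        assert intersect_bases(a, b) == intersect_bases(b, a)
        assert union_bases(a, b) == union_bases(b, a)
        # split every interval of a into abutting halves: nothing changes
        frag = []
        for iv in a:
            if len(iv) > 1:
                mid = iv.start + len(iv) // 2
                frag += [GenomicInterval(iv.chrom, iv.start, mid),
                         GenomicInterval(iv.chrom, mid, iv.end)]
            else:
                frag.append(iv)
        a_frag = IntervalSet(frag)
        assert intersect_bases(a_frag, b) == intersect_bases(a, b)
        assert union_bases(a_frag, b) == union_bases(a, b)


class TestOverlappingSubset:
    def test_whole_interval_retained(self):
        a = iset(("chr1", 0, 10))
        out = overlapping_subset(a, iset(("chr1", 5, 6)))
        assert out.intervals == a.intervals

    def test_half_open_boundary_excluded(self):
        assert len(overlapping_subset(iset(("chr1", 0, 10)), iset(("chr1", 10, 20)))) == 0

    def test_selects_only_overlapping_peaks(self, toy_genome):
        a = iset(("chr1", 0, 10), ("chr1", 100, 120), ("chr1", 300, 310), genome=toy_genome)
        b = iset(("chr1", 5, 8), ("chr1", 110, 130), genome=toy_genome)
        out = overlapping_subset(a, b)
        assert [(iv.start, iv.end) for iv in out] == [(0, 10), (100, 120)]
        assert out.intervals == oracle_overlapping_subset(a, b, toy_genome).intervals


class TestSubtract:
    def test_blacklist_clips_and_splits(self, toy_genome):
        a = iset(("chr1", 0, 100), genome=toy_genome)
        bl = iset(("chr1", 40, 60), genome=toy_genome)
        out = subtract_intervals(a, bl)
        assert [(iv.start, iv.end) for iv in out] == [(0, 40), (60, 100)]
        assert bases_of(out, toy_genome)["chr1"].sum() == 80


class TestNearestTss:
    genes = [
        GeneAnnotation("gB", "chr1", 300),
        GeneAnnotation("gA", "chr1", 1000),
        GeneAnnotation("gC", "chr2", 150),
    ]

    def test_tss_inside_interval_wins_with_distance_zero(self):
        hit = nearest_tss(GenomicInterval("chr2", 100, 200), self.genes, 500)
        assert hit == "gC"

    def test_brute_force_distance(self):
        # gB at 300 is 101 bases from the last covered base (199); gA is 800 away
        assert nearest_tss(GenomicInterval("chr1", 100, 200), self.genes, 500) == "gB"

    def test_none_beyond_max_distance(self):
        assert nearest_tss(GenomicInterval("chr1", 100, 200), self.genes, 100) is None

    def test_tie_broken_by_lexicographic_gene_id(self):
        genes = [GeneAnnotation("z", "chr1", 90), GeneAnnotation("a", "chr1", 310)]
        # both 11 bases away from [101, 300)
        assert nearest_tss(GenomicInterval("chr1", 101, 300), genes, 1000) == "a"


class TestSignal:
    def test_uniform_track(self):
        track = CoverageTrack([("chr1", 0, 100, 2.0)])
        assert signal_in_interval(track, GenomicInterval("chr1", 10, 20)) == 20.0

    def test_outside_steps_is_zero(self):
        track = CoverageTrack([("chr1", 0, 100, 2.0)])
        assert signal_in_interval(track, GenomicInterval("chr1", 500, 600)) == 0.0
        assert signal_in_interval(track, GenomicInterval("chr2", 0, 10)) == 0.0

    def test_step_boundary_weighting(self, toy_genome):
        track = CoverageTrack([("chr1", 0, 10, 1.0), ("chr1", 10, 30, 3.0)])
        iv = GenomicInterval("chr1", 5, 15)
        assert signal_in_interval(track, iv) == 20.0 == oracle_signal(track, iv, toy_genome)

    def test_additive_over_partition(self):
        track = CoverageTrack([("chr1", 0, 10, 1.0), ("chr1", 12, 30, 3.0)])
        whole = signal_in_interval(track, GenomicInterval("chr1", 0, 30))
        parts = sum(
            signal_in_interval(track, GenomicInterval("chr1", s, e))
            for s, e in [(0, 7), (7, 20), (20, 30)]
        )
        assert whole == pytest.approx(parts)
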