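import copy

import pytest
from hypothesis import given, settings, strategies as st

from txreconstruct import alignment_io, tag_clustering
from txreconstruct.core import GenomicInterval, ReadAlignment, TagCluster
from txreconstruct.read_polishing import (
    ClusterIndex,
    classify_read,
    distinct_exon_count,
    distinct_internal_border_count,
    extend_read_ends,
    unify_borders,
)
from conftest import truth_internal_borders


def cluster(kind, chrom, strand, start, end, summit, cid="X1"):
    return TagCluster(
        id=cid,
        interval=GenomicInterval(chrom, start, end, strand),
        summit=summit,
        score=10,
        kind=kind,
    )


def read(blocks, strand="+", chrom="chr1", rid="r"):
    return ReadAlignment(read_id=rid, chrom=chrom, strand=strand, blocks=list(blocks))


EMPTY = ClusterIndex([])


class TestExtension:
    def test_extends_to_upstream_summit_within_limit(self):
        tss = ClusterIndex([cluster("TSS", "chr1", "+", 995, 1005, 1000)])
        r = extend_read_ends(read([(1050, 1200)]), tss, EMPTY, max_extension=100)
        assert r.blocks == [(1000, 1200)]
        assert r.tss_supported and r.extended_5p == 50
        assert classify_read(r) == "tss_only"

    def test_summit_beyond_limit_leaves_read_unchanged(self):
        tss = ClusterIndex([cluster("TSS", "chr1", "+", 895, 905, 900)])
        r = extend_read_ends(read([(1050, 1200)]), tss, EMPTY, max_extension=100)
        assert r.blocks == [(1050, 1200)] and not r.tss_supported
        assert classify_read(r) == "unsupported"

    def test_end_inside_cluster_is_supported_without_moving(self):
        tss = ClusterIndex([cluster("TSS", "chr1", "+", 1040, 1060, 1050)])
        r = extend_read_ends(read([(1050, 1200)]), tss, EMPTY)
        assert r.blocks == [(1050, 1200)] and r.tss_supported and r.extended_5p == 0

    def test_minus_strand_mirror(self):
        # 5' of a minus read is its right end; TSS summit downstream-right
        tss = ClusterIndex([cluster("TSS", "chr1", "-", 1245, 1255, 1250)])
        pas = ClusterIndex([cluster("PAS", "chr1", "-", 995, 1005, 1000)])
        r = extend_read_ends(read([(1050, 1200)], strand="-"), tss, pas)
        assert r.blocks == [(1000, 1251)]
        assert classify_read(r) == "complete"

    def test_extension_boundary_exactly_at_limit(self):
        tss_at = ClusterIndex([cluster("TSS", "chr1", "+", 995, 1005, 1000)])
        r = extend_read_ends(read([(1100, 1300)]), tss_at, EMPTY, max_extension=100)
        assert r.blocks[0][0] == 1000  # distance exactly 100 is allowed
        r2 = extend_read_ends(read([(1101, 1300)]), tss_at, EMPTY, max_extension=100)
        assert r2.blocks[0][0] == 1101  # distance 101 is not

    def test_block_count_preserved_and_only_terminal_block_moves(self):
        tss = ClusterIndex([cluster("TSS", "chr1", "+", 995, 1005, 1000)])
        pas = ClusterIndex([cluster("PAS", "chr1", "+", 1995, 2005, 2000)])
        r = extend_read_ends(read([(1050, 1200), (1400, 1950)]), tss, pas)
        assert r.blocks == [(1000, 1200), (1400, 2001)]
        assert classify_read(r) == "complete"


class TestBorderUnification:
    def make_locus(self, right_borders):
        reads = []
        for i, b in enumerate(right_borders):
            reads.append(read([(1000, b), (1300, 1400)], rid=f"r{i}"))
        return reads

    def test_majority_vote(self):
        borders = [1200] * 4 + [1202] * 2 + [1209]
        reads = unify_borders(self.make_locus(borders))
        assert {r.blocks[0][1] for r in reads} == {1200}

    def test_beyond_offset_stays_split(self):
        borders = [1200] * 3 + [1215] * 3
        reads = unify_borders(self.make_locus(borders))
        assert {r.blocks[0][1] for r in reads} == {1200, 1215}

    def test_offset_boundary(self):
        merged = unify_borders(self.make_locus([1200] * 4 + [1210]))
        assert {r.blocks[0][1] for r in merged} == {1200}  # distance 10 merges
        split = unify_borders(self.make_locus([1200] * 4 + [1211]))
        assert {r.blocks[0][1] for r in split} == {1200, 1211}  # 11 does not

    def test_single_read_locus_unchanged(self):
        r = read([(1000, 1100), (1200, 1300)])
        assert unify_borders([r])[0].blocks == [(1000, 1100), (1200, 1300)]

    def test_anchored_termini_never_rewritten(self):
        reads = self.make_locus([1200] * 4)
        stray = read([(1003, 1200), (1300, 1400)], rid="stray")
        stray.tss_supported = True  # 5' anchored at 1003
        reads.append(stray)
        unify_borders(reads)
        assert stray.blocks[0][0] == 1003
        # unanchored 5' termini do participate and converge on the majority
        assert all(r.blocks[0][0] == 1000 for r in reads[:-1])

    def test_idempotent(self, default_sim):
        _, paths = default_sim
        reads = alignment_io.load_long_reads(paths.long_bam)
        once = unify_borders(copy.deepcopy(reads))
        twice = unify_borders(copy.deepcopy(once))
        assert [r.blocks for r in once] == [r.blocks for r in twice]


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.integers(min_value=-4, max_value=4),
            st.integers(min_value=-4, max_value=4),
        ),
        min_size=1,
        max_size=20,
    )
)
def test_unification_never_breaks_block_order(jitters):
    reads = [
        read([(1000, 1150 + a), (1250 + b, 1400)], rid=f"r{i}")
        for i, (a, b) in enumerate(jitters)
    ]
    for r in unify_borders(reads):
        r.validate()
        assert len(r.blocks) == 2


def test_fixture_unification_restores_true_splice_sites(default_sim):
    """After majority voting, the distinct internal borders are exactly the
    simulated splice sites, and the unique-exon count shrinks."""
    truth, paths = default_sim
    reads = alignment_io.load_long_reads(paths.long_bam)
    tss = tag_clustering.call_tag_clusters(
        alignment_io.load_tag_profile(paths.tss_bams, "TSS"), "TSS"
    )
    pas = tag_clustering.call_tag_clusters(
        alignment_io.load_tag_profile(paths.pas_bams, "PAS"), "PAS"
    )
    ti, pi = ClusterIndex(tss), ClusterIndex(pas)
    for r in reads:
        extend_read_ends(r, ti, pi)
    exons_before = distinct_exon_count(reads)
    borders_before = distinct_internal_border_count(reads)
    unify_borders(reads)
    assert distinct_internal_border_count(reads) == len(truth_internal_borders(truth))
    assert distinct_exon_count(reads) < exons_before
    assert distinct_internal_border_count(reads) < borders_before
    for r in reads:
        r.validate()
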