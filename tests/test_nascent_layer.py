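import numpy as np
import pytest

from txreconstruct.core import GeneModel, GenomicInterval, NascentInterval, TransientRNA
from txreconstruct.nascent_layer import (
    append_rt_tails,
    call_nascent_intervals,
    call_transient_rnas,
    classify_orientation,
)


def track(segments, size=10_000, chrom="chr1", strand="+"):
    depth = np.zeros(size, dtype=np.int32)
    for s, e, d in segments:
        depth[s:e] += d
    return {(chrom, strand): depth}


def gene(start, end, strand="+", gid="G1", chrom="chr1"):
    return GeneModel(
        id=gid,
        interval=GenomicInterval(chrom, start, end, strand),
        confidence="HC",
        transcripts=[],
    )


class TestIntervalCalling:
    def test_gap_bridging(self):
        ivs = call_nascent_intervals(track([(0, 300, 1), (350, 600, 1)]), max_gap=100)
        assert [(i.interval.start, i.interval.end) for i in ivs] == [(0, 600)]

    def test_gap_beyond_limit_splits(self):
        ivs = call_nascent_intervals(track([(0, 300, 1), (450, 600, 1)]), max_gap=100)
        assert [(i.interval.start, i.interval.end) for i in ivs] == [(0, 300), (450, 600)]

    def test_short_island_dropped(self):
        assert call_nascent_intervals(track([(100, 140, 3)]), min_interval_length=50) == []

    def test_empty_track(self):
        assert call_nascent_intervals(track([])) == []

    def test_min_depth_threshold(self):
        ivs = call_nascent_intervals(track([(0, 200, 1), (200, 400, 3)]), min_depth=2)
        assert [(i.interval.start, i.interval.end) for i in ivs] == [(200, 400)]


class TestRTTails:
    def test_overhang_becomes_tail(self):
        g = gene(4000, 5000)
        ivs = call_nascent_intervals(track([(4800, 5400, 2)]))
        append_rt_tails([g], ivs)
        assert g.rt_tail == 400

    def test_no_downstream_signal_means_zero(self):
        g = gene(4000, 5000)
        ivs = call_nascent_intervals(track([(4200, 4900, 2)]))
        append_rt_tails([g], ivs)
        assert g.rt_tail == 0

    def test_tail_truncated_at_next_gene(self):
        g1, g2 = gene(4000, 5000, gid="G1"), gene(5200, 6000, gid="G2")
        ivs = call_nascent_intervals(track([(4800, 5400, 2)]))
        append_rt_tails([g1, g2], ivs)
        assert g1.rt_tail == 200

    def test_detached_interval_within_link_distance(self):
        g = gene(4000, 5000)
        ivs = call_nascent_intervals(track([(5050, 5400, 2)]))
        append_rt_tails([g], ivs, link_distance=100)
        assert g.rt_tail == 350
        ivs = call_nascent_intervals(track([(5150, 5400, 2)]))
        g.rt_tail = 0
        append_rt_tails([g], ivs, link_distance=100)
        assert g.rt_tail == 0  # 150 bp away: not linked

    def test_minus_strand_tail_extends_left(self):
        g = gene(4000, 5000, strand="-")
        ivs = call_nascent_intervals(track([(3700, 4200, 2)], strand="-"))
        append_rt_tails([g], ivs)
        assert g.rt_tail == 300


class TestTransients:
    def test_gene_free_interval_is_transient(self):
        g = gene(4000, 5000)
        ivs = call_nascent_intervals(track([(8000, 8400, 2)]))
        pieces = append_rt_tails([g], ivs)
        out = call_transient_rnas(pieces, [g])
        assert len(out) == 1
        assert (out[0].interval.start, out[0].interval.end) == (8000, 8400)

    def test_same_strand_gene_overlap_is_within_gene_not_transient(self):
        g = gene(4000, 5000)
        ivs = call_nascent_intervals(track([(4100, 4900, 2)]))
        pieces = append_rt_tails([g], ivs)
        assert call_transient_rnas(pieces, [g]) == []
        assert {p.classification for p in pieces} == {"within_gene"}

    def test_antisense_coverage_is_transient(self):
        g = gene(4000, 5000, strand="+")
        ivs = call_nascent_intervals(track([(4100, 4900, 2)], strand="-"))
        pieces = append_rt_tails([g], ivs)
        assert len(call_transient_rnas(pieces, [g])) == 1

    def test_partition_into_three_classes(self):
        g = gene(4000, 5000)
        ivs = call_nascent_intervals(track([(4500, 5300, 2), (8000, 8500, 1)]))
        pieces = append_rt_tails([g], ivs)
        call_transient_rnas(pieces, [g])
        classes = sorted(p.classification for p in pieces)
        assert classes == ["rt_tail", "transient", "within_gene"]
        covered = sum(len(p.interval) for p in pieces)
        assert covered == sum(len(i.interval) for i in ivs)


class TestOrientation:
    def unit(self, start, end, strand):
        return TransientRNA(id="t", interval=GenomicInterval("chr1", start, end, strand))

    def test_antisense_intergenic_unclassified(self):
        ref = [GenomicInterval("chr1", 1000, 2000, "+")]
        anti = self.unit(1500, 1800, "-")
        inter = self.unit(5000, 5400, "-")
        classify_orientation([anti, inter], ref)
        assert anti.orientation_class == "antisense"
        assert inter.orientation_class == "intergenic"
        no_ref = self.unit(1500, 1800, "-")
        classify_orientation([no_ref], None)
        assert no_ref.orientation_class == "unclassified"

    def test_same_strand_reference_overlap_is_not_antisense(self):
        ref = [GenomicInterval("chr1", 1000, 2000, "-")]
        u = self.unit(1500, 1800, "-")
        classify_orientation([u], ref)
        assert u.orientation_class == "intergenic"


class TestFixtureRecovery:
    def test_transient_units_recovered_with_high_jaccard(self, default_run):
        truth, _, _, result = default_run
        assert len(result.transients) == len(truth.transients)
        for unit in truth.transients:
            best = max(
                unit.jaccard(t.interval)
                for t in result.transients
                if t.interval.strand == unit.strand
            )
            assert best >= 0.9

    def test_rt_tail_lengths_recovered_within_gap_tolerance(self, default_run):
        truth, _, cfg, result = default_run
        called = {g.id: g for g in result.genes}
        for g in truth.genes:
            span = GenomicInterval(g.chrom, g.start, g.end, g.strand)
            hit = max(
                result.genes,
                key=lambda cg: cg.interval.overlap_len(span),
            )
            if g.rt_tail > 0:
                assert abs(hit.rt_tail - g.rt_tail) <= cfg.nascent_max_gap, g.name

    def test_orientation_of_fixture_transients_against_truth_genes(self, default_sim, default_run):
        truth, _, _, result = default_run
        ref = [
            GenomicInterval(g.chrom, g.start, g.end, g.strand) for g in truth.genes
        ]
        classify_orientation(result.transients, ref)
        classes = sorted(t.orientation_class for t in result.transients)
        expected = []
        for unit in truth.transients:
            anti = any(
                r.chrom == unit.chrom and r.strand != unit.strand
                and r.start < unit.end and unit.start < r.end
                for r in ref
            )
            expected.append("antisense" if anti else "intergenic")
        assert classes == sorted(expected)
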