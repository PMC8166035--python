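from txreconstruct.core import ReadAlignment, TranscriptModel
from txreconstruct.model_calling import (
    assign_tiers_and_rescue,
    cluster_genes,
    collapse_reads,
    filter_minor_isoforms,
)
from txreconstruct.simdata import compare_to_truth


def read(blocks, tss="T1", pas="P1", rid="r", strand="+", error=False):
    r = ReadAlignment(read_id=rid, chrom="chr1", strand=strand, blocks=list(blocks))
    r.tss_id, r.pas_id = tss, pas
    r.error_flag = error
    return r


def tx(blocks, conf="HC", support=10, strand="+", chrom="chr1", tss="T", pas="P"):
    if conf == "MC":
        pas = None
    if conf == "LC":
        tss = pas = None
    return TranscriptModel(
        id="", chrom=chrom, strand=strand, blocks=[tuple(b) for b in blocks],
        confidence=conf, support=support, tss_id=tss, pas_id=pas,
    )


class TestCollapse:
    def test_identical_reads_collapse_with_support(self):
        reads = [read([(0, 100), (200, 300)], rid=f"r{i}") for i in range(7)]
        out = collapse_reads(reads)
        assert len(out) == 1
        assert out[0].support == 7 and out[0].confidence == "HC"

    def test_distinct_structures_stay_separate(self):
        a = read([(0, 100), (200, 300)], rid="a")
        b = read([(0, 300)], rid="b")  # retained intron
        assert len(collapse_reads([a, b])) == 2

    def test_lower_tier_folds_into_higher(self):
        complete = read([(0, 100)], rid="c")
        tss_only = read([(0, 100)], pas=None, rid="t")
        out = collapse_reads([complete, tss_only])
        assert len(out) == 1
        assert out[0].confidence == "HC" and out[0].support == 2

    def test_error_flagged_reads_excluded(self):
        good = read([(0, 100)], rid="g")
        bad = read([(0, 100)], rid="b", error=True)
        out = collapse_reads([good, bad])
        assert len(out) == 1 and out[0].support == 1


class TestRescue:
    def test_lc_inside_hc_locus_discarded(self):
        hc = tx([(0, 500)], "HC")
        lc = tx([(100, 300)], "LC")
        assert assign_tiers_and_rescue([hc, lc]) == [hc]

    def test_mc_in_empty_locus_rescued(self):
        hc = tx([(0, 500)], "HC")
        mc = tx([(5000, 5400)], "MC")
        assert assign_tiers_and_rescue([hc, mc]) == [hc, mc]

    def test_two_lc_only_loci_both_kept(self):
        a = tx([(0, 300)], "LC")
        b = tx([(5000, 5300)], "LC")
        assert assign_tiers_and_rescue([a, b]) == [a, b]

    def test_opposite_strand_hc_does_not_suppress(self):
        hc = tx([(0, 500)], "HC", strand="-")
        lc = tx([(100, 300)], "LC", strand="+")
        assert assign_tiers_and_rescue([hc, lc]) == [hc, lc]


class TestMinorIsoformFilter:
    def test_below_one_percent_removed(self):
        major = tx([(0, 500)], support=199)
        minor = tx([(0, 200), (300, 500)], support=1)  # 0.5% of 200 reads
        assert filter_minor_isoforms([major, minor]) == [major]

    def test_exactly_one_percent_kept(self):
        major = tx([(0, 500)], support=198)
        minor = tx([(0, 200), (300, 500)], support=2)  # exactly 1% of 200
        assert len(filter_minor_isoforms([major, minor])) == 2

    def test_single_isoform_gene_always_kept(self):
        only = tx([(0, 500)], support=1)
        assert filter_minor_isoforms([only]) == [only]

    def test_genes_filtered_independently(self):
        g1_major = tx([(0, 500)], support=199)
        g1_minor = tx([(0, 500), (600, 700)], support=1)
        far = tx([(10_000, 10_500)], support=1)
        kept = filter_minor_isoforms([g1_major, g1_minor, far])
        assert far in kept and g1_minor not in kept


class TestGeneClustering:
    def test_shared_exon_merges_into_one_gene(self):
        a = tx([(0, 100), (200, 400)])
        b = tx([(0, 100), (300, 400)])
        genes, txs, fusions = cluster_genes([a, b])
        assert len(genes) == 1 and not fusions
        assert genes[0].id == "HC_gene_00001"
        assert {t.gene_id for t in txs} == {"HC_gene_00001"}
        assert genes[0].interval.start == 0 and genes[0].interval.end == 400

    def test_intron_only_overlap_does_not_merge(self):
        outer = tx([(0, 100), (900, 1000)])
        nested = tx([(300, 600)])  # inside the intron
        genes, _, _ = cluster_genes([outer, nested])
        assert len(genes) == 2

    def test_antisense_overlap_never_merges(self):
        a = tx([(0, 400)], strand="+")
        b = tx([(100, 500)], strand="-")
        genes, _, _ = cluster_genes([a, b])
        assert len(genes) == 2

    def test_bridging_transcript_becomes_fusion(self):
        g1a = tx([(0, 100), (200, 400)], support=20, tss="T1", pas="P1")
        g1b = tx([(0, 100), (250, 400)], support=15, tss="T1", pas="P1")
        g2a = tx([(1000, 1200), (1300, 1500)], support=20, tss="T2", pas="P2")
        bridge = tx([(0, 100), (200, 450), (1000, 1200), (1300, 1500)],
                    support=2, tss="T1", pas="P2")
        genes, txs, fusions = cluster_genes([g1a, g1b, g2a, bridge])
        assert len(fusions) == 1 and fusions[0].support == 2
        assert len(genes) == 2
        assert fusions[0].spanned_gene_ids == [g.id for g in genes]
        # partition: every remaining transcript in exactly one gene, fusion in none
        assert sorted(t.id for t in txs) == sorted(
            tid for g in genes for tid in g.transcripts
        )

    def test_gene_confidence_is_best_member_tier(self):
        hc = tx([(0, 400)], "HC")
        mc = tx([(100, 500)], "MC")
        genes, _, _ = cluster_genes([hc, mc])
        assert genes[0].confidence == "HC"


class TestFixtureRecovery:
    def test_recovers_all_resolvable_isoforms_exactly(self, default_run):
        """Every simulated isoform above the minor-isoform regime is called
        as an HC transcript with exactly the true block structure, and every
        called HC border sits on a true border."""
        truth, _, _, result = default_run
        report = compare_to_truth(
            result.transcripts, result.genes, result.transients, truth,
            tolerance=0, min_abundance=0.02,
        )
        assert report["isoform_recall"] == 1.0
        true_borders = set()
        for g in truth.genes:
            for iso in g.isoforms:
                for s, e in iso.exons:
                    true_borders.add((g.chrom, g.strand, s))
                    true_borders.add((g.chrom, g.strand, e))
        for t in result.transcripts:
            if t.confidence != "HC":
                continue
            for s, e in t.blocks:
                for p in (s, e):
                    assert any(
                        key[0] == t.chrom and key[1] == t.strand and abs(key[2] - p) <= 100
                        for key in true_borders
                    ), (t.id, t.blocks)

    def test_gene_counts_match_ground_truth(self, default_run):
        truth, _, _, result = default_run
        assert result.summary.genes["HC"] == len(truth.genes)
        assert result.summary.genes["MC"] == result.summary.genes["LC"] == 0

    def test_support_tracks_isoform_abundance(self, default_run):
        truth, _, _, result = default_run
        # the dominant isoform of each gene has the top-supported transcript
        for g in truth.genes:
            top_iso = max(g.isoforms, key=lambda i: i.abundance)
            called = [
                t for t in result.transcripts
                if t.chrom == g.chrom and t.strand == g.strand
                and g.start <= t.start and t.end <= g.end + 1
            ]
            assert called, g.name
            best = max(called, key=lambda t: t.support)
            assert best.blocks == [tuple(b) for b in top_iso.exons], g.name
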