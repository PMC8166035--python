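"""End-to-end pipeline: tag clustering -> read polishing -> error
detection -> transcript/gene calling -> optional nascent layer -> export.

The pipeline is deterministic: two runs on identical inputs produce
byte-identical output files.
"""

from __future__ import annotations

import json
import logging
import os
import statistics
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence

import yaml

from . import alignment_io, bedio, error_detection, model_calling, nascent_layer, read_polishing, tag_clustering
from .core import (
    CONSTITUTIVE_FRACTION,
    LINK_DISTANCE,
    MAX_BORDER_OFFSET,
    MAX_EXTENSION,
    MIN_GENE_OVERLAP_BP,
    MIN_INTERVAL_LENGTH,
    MIN_ISOFORM_FRACTION,
    MIN_MAPQ,
    MIN_TAIL,
    NASCENT_MAX_GAP,
    NASCENT_MIN_DEPTH,
    TAG_MAX_GAP,
    TAG_MIN_COUNT,
    FusionTranscript,
    GeneModel,
    TranscriptModel,
    TransientRNA,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    long_read_bams: List[str]
    tss_bams: List[str]
    pas_bams: List[str]
    nascent_bams: List[str] = field(default_factory=list)
    reference_annotation: Optional[str] = None
    out_dir: str = "txreconstruct_out"
    min_mapq: int = MIN_MAPQ
    reads_reverse_complemented: bool = False
    tag_max_gap: int = TAG_MAX_GAP
    min_tag_count: int = TAG_MIN_COUNT
    min_sample_fraction: float = 0.0
    max_extension: int = MAX_EXTENSION
    max_border_offset: int = MAX_BORDER_OFFSET
    constitutive_fraction: float = CONSTITUTIVE_FRACTION
    min_isoform_fraction: float = MIN_ISOFORM_FRACTION
    min_gene_overlap_bp: int = MIN_GENE_OVERLAP_BP
    nascent_min_depth: int = NASCENT_MIN_DEPTH
    nascent_max_gap: int = NASCENT_MAX_GAP
    min_interval_length: int = MIN_INTERVAL_LENGTH
    link_distance: int = LINK_DISTANCE
    min_tail: int = MIN_TAIL
    write_gff3: bool = True
    write_debug_reads: bool = False

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def validate(self) -> None:
        required = ("long_read_bams", "tss_bams", "pas_bams")
        for name in required:
            if not getattr(self, name):
                raise ValueError(f"config: {name} is required")
        for name in required:
            for p in getattr(self, name):
                if not os.path.exists(p):
                    raise FileNotFoundError(f"config: {name} entry missing: {p}")


@dataclass
class RunSummary:
    tss_clusters: int = 0
    pas_clusters: int = 0
    n_long_reads: int = 0
    fraction_complete_before: float = 0.0
    fraction_complete_after: float = 0.0
    distinct_exons_before: int = 0
    distinct_exons_after: int = 0
    flagged_read_fraction: float = 0.0
    genes: Dict[str, int] = field(default_factory=dict)
    transcripts: Dict[str, int] = field(default_factory=dict)
    fusion_transcripts: int = 0
    transient_rnas: Optional[int] = None
    rt_tail_prevalence: Optional[float] = None
    rt_tail_median: Optional[float] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class PipelineResult:
    summary: RunSummary
    genes: List[GeneModel]
    transcripts: List[TranscriptModel]
    fusions: List[FusionTranscript]
    transients: List[TransientRNA]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    probe = os.path.join(config.out_dir, ".writable")
    try:
        with open(probe, "w"):
            pass
        os.remove(probe)
    except OSError as exc:
        raise OSError(f"output directory {config.out_dir} is not writable: {exc}")

    summary = RunSummary()

    # --- stage 1: tag clustering ---
    log.info("stage tag_clustering: calling TSS and PAS clusters")
    tss_profile = alignment_io.load_tag_profile(config.tss_bams, "TSS")
    pas_profile = alignment_io.load_tag_profile(config.pas_bams, "PAS")
    rep_profiles_tss = rep_profiles_pas = None
    if config.min_sample_fraction > 0:
        rep_profiles_tss = [alignment_io.load_tag_profile([p], "TSS") for p in config.tss_bams]
        rep_profiles_pas = [alignment_io.load_tag_profile([p], "PAS") for p in config.pas_bams]
    tss = tag_clustering.call_tag_clusters(
        tss_profile, "TSS", config.tag_max_gap, config.min_tag_count,
        config.min_sample_fraction, rep_profiles_tss,
    )
    pas = tag_clustering.call_tag_clusters(
        pas_profile, "PAS", config.tag_max_gap, config.min_tag_count,
        config.min_sample_fraction, rep_profiles_pas,
    )
    summary.tss_clusters = len(tss)
    summary.pas_clusters = len(pas)

    # --- stage 2: read polishing ---
    log.info("stage read_polishing: extension and border unification")
    reads = []
    for p in config.long_read_bams:
        reads.extend(
            alignment_io.load_long_reads(p, config.min_mapq, config.reads_reverse_complemented)
        )
    reads.sort(key=lambda r: (r.chrom, r.start, r.end, r.read_id))
    summary.n_long_reads = len(reads)
    tss_index = read_polishing.ClusterIndex(tss)
    pas_index = read_polishing.ClusterIndex(pas)

    n_before = 0
    for r in reads:
        in_tss = tss_index.containing(r.chrom, r.strand, r.five_prime()) is not None
        in_pas = pas_index.containing(r.chrom, r.strand, r.three_prime()) is not None
        if in_tss and in_pas:
            n_before += 1
    for r in reads:
        read_polishing.extend_read_ends(r, tss_index, pas_index, config.max_extension)
    n_after = sum(1 for r in reads if read_polishing.classify_read(r) == "complete")
    if reads:
        summary.fraction_complete_before = n_before / len(reads)
        summary.fraction_complete_after = n_after / len(reads)

    summary.distinct_exons_before = read_polishing.distinct_exon_count(reads)
    read_polishing.unify_borders(reads, config.max_border_offset)
    summary.distinct_exons_after = read_polishing.distinct_exon_count(reads)

    # --- stage 3: error detection ---
    log.info("stage error_detection: under-splitting check")
    _, flagged_frac = error_detection.flag_all(reads, config.constitutive_fraction)
    summary.flagged_read_fraction = flagged_frac
    log.info("flagged-read fraction: %.3f", flagged_frac)

    # --- stage 4: transcript and gene calling ---
    log.info("stage model_calling: collapse, tiers, genes, fusions")
    transcripts = model_calling.collapse_reads(reads)
    transcripts = model_calling.assign_tiers_and_rescue(transcripts)
    transcripts = model_calling.filter_minor_isoforms(
        transcripts, config.min_isoform_fraction, config.min_gene_overlap_bp
    )
    genes, transcripts, fusions = model_calling.cluster_genes(
        transcripts, config.min_gene_overlap_bp
    )
    for tier in ("HC", "MC", "LC"):
        summary.genes[tier] = sum(1 for g in genes if g.confidence == tier)
        summary.transcripts[tier] = sum(1 for t in transcripts if t.confidence == tier)
    summary.fusion_transcripts = len(fusions)

    # --- stage 5: nascent layer (optional) ---
    transients: List[TransientRNA] = []
    if config.nascent_bams:
        log.info("stage nascent_layer: intervals, RT tails, transient RNAs")
        track = alignment_io.load_nascent_coverage(config.nascent_bams)
        intervals = nascent_layer.call_nascent_intervals(
            track, config.nascent_min_depth, config.nascent_max_gap, config.min_interval_length
        )
        pieces = nascent_layer.append_rt_tails(
            genes, intervals, config.link_distance, config.min_tail
        )
        transients = nascent_layer.call_transient_rnas(
            pieces, genes, config.min_interval_length
        )
        reference = None
        if config.reference_annotation:
            reference = bedio.read_reference_annotation(config.reference_annotation)
        nascent_layer.classify_orientation(transients, reference)
        summary.transient_rnas = len(transients)
        tails = [g.rt_tail for g in genes if g.rt_tail > config.min_tail]
        summary.rt_tail_prevalence = len(tails) / len(genes) if genes else 0.0
        summary.rt_tail_median = float(statistics.median(tails)) if tails else 0.0

    # --- stage 6: export ---
    log.info("stage export: writing BED/GFF3/JSON to %s", config.out_dir)
    out = config.out_dir
    bedio.write_tag_clusters_bed6(os.path.join(out, "tss_clusters.bed"), tss)
    bedio.write_tag_clusters_bed6(os.path.join(out, "pas_clusters.bed"), pas)
    bedio.write_transcripts_bed12(os.path.join(out, "transcripts.bed"), transcripts)
    bedio.write_transcripts_bed12(os.path.join(out, "fusion_transcripts.bed"), fusions)
    bedio.write_genes_bed6(os.path.join(out, "genes.bed"), genes)
    bedio.write_transients_bed6(os.path.join(out, "transient_rnas.bed"), transients)
    bedio.write_rt_tails_bed6(os.path.join(out, "rt_tails.bed"), genes)
    if config.write_gff3:
        bedio.write_gff3(os.path.join(out, "models.gff3"), genes, transcripts)
    if config.write_debug_reads:
        bedio.write_reads_bed12(os.path.join(out, "corrected_reads.bed"), reads)
    with open(os.path.join(out, "run_summary.json"), "w") as fh:
        fh.write(summary.to_json() + "\n")

    return PipelineResult(
        summary=summary,
        genes=genes,
        transcripts=transcripts,
        fusions=fusions,
        transients=transients,
    )
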