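"""Transcript and gene model calling.

Error-free polished reads with identical exon structure collapse into
transcripts tiered HC/MC/LC by TSS/PAS support; MC/LC transcripts inside
HC loci are presumed fragments and dropped; minor isoforms (<1% of the
gene's reads) are skipped; same-strand transcripts with exonic overlap
cluster into genes; and transcripts bridging two independently anchored
gene groups are set aside as fusion transcripts.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Dict, List, Sequence, Tuple

from .core import (
    MIN_GENE_OVERLAP_BP,
    MIN_ISOFORM_FRACTION,
    FusionTranscript,
    GeneModel,
    GenomicInterval,
    ReadAlignment,
    TranscriptModel,
    TIER_ORDER,
    tier_of,
)

Block = Tuple[int, int]


def collapse_reads(reads: Sequence[ReadAlignment]) -> List[TranscriptModel]:
    """Merge reads with identical block structures into transcripts.

    A lower-tier read with the same exact structure folds into the
    higher-tier transcript (identical structure, identical molecule class).
    """
    buckets: Dict[Tuple, List[ReadAlignment]] = defaultdict(list)
    for r in reads:
        if r.error_flag:
            continue
        buckets[r.block_key()].append(r)
    transcripts: List[TranscriptModel] = []
    for key in sorted(buckets, key=lambda k: (k[0], k[2][0][0], k[1])):
        members = buckets[key]
        chrom, strand, blocks = key
        best = max(
            members,
            key=lambda r: TIER_ORDER[tier_of(r.tss_id, r.pas_id)],
        )
        transcripts.append(
            TranscriptModel(
                id="",
                chrom=chrom,
                strand=strand,
                blocks=[tuple(b) for b in blocks],
                confidence=tier_of(best.tss_id, best.pas_id),
                support=len(members),
                tss_id=best.tss_id,
                pas_id=best.pas_id,
            )
        )
    return transcripts


def assign_tiers_and_rescue(transcripts: Sequence[TranscriptModel]) -> List[TranscriptModel]:
    """Drop MC/LC transcripts overlapping any HC locus on the same strand.

    MC/LC models may come from fragmented molecules; they are retained only
    to rescue loci where no complete read exists.
    """
    hc_spans: Dict[Tuple[str, str], List[Tuple[int, int]]] = defaultdict(list)
    for t in transcripts:
        if t.confidence == "HC":
            hc_spans[(t.chrom, t.strand)].append((t.start, t.end))
    kept: List[TranscriptModel] = []
    for t in transcripts:
        if t.confidence == "HC":
            kept.append(t)
            continue
        spans = hc_spans.get((t.chrom, t.strand), [])
        if any(t.start < e and s < t.end for s, e in spans):
            continue
        kept.append(t)
    return kept


def _exonic_overlap(a: TranscriptModel, b: TranscriptModel, min_bp: int) -> bool:
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    if a.start >= b.end or b.start >= a.end:
        return False
    for s1, e1 in a.blocks:
        for s2, e2 in b.blocks:
            if min(e1, e2) - max(s1, s2) >= min_bp:
                return True
    return False


def _components(
    transcripts: List[TranscriptModel], min_bp: int
) -> List[List[TranscriptModel]]:
    """Connected components under same-strand exonic overlap."""
    by_key: Dict[Tuple[str, str], List[TranscriptModel]] = defaultdict(list)
    for t in transcripts:
        by_key[(t.chrom, t.strand)].append(t)
    comps: List[List[TranscriptModel]] = []
    for key in sorted(by_key):
        group = sorted(by_key[key], key=lambda t: (t.start, t.end, tuple(t.blocks)))
        parent = list(range(len(group)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                if group[j].start >= group[i].end:
                    break
                if _exonic_overlap(group[i], group[j], min_bp):
                    parent[find(i)] = find(j)
        by_root: Dict[int, List[TranscriptModel]] = defaultdict(list)
        for i, t in enumerate(group):
            by_root[find(i)].append(t)
        comps.extend(sorted(by_root.values(), key=lambda c: c[0].start))
    return comps


def filter_minor_isoforms(
    transcripts: Sequence[TranscriptModel],
    min_isoform_fraction: float = MIN_ISOFORM_FRACTION,
    min_gene_overlap_bp: int = MIN_GENE_OVERLAP_BP,
) -> List[TranscriptModel]:
    """Skip isoforms supported by < min_isoform_fraction of the gene's reads.

    Provisional genes are overlap components of the surviving transcripts;
    removal is a strict less-than, and the top-supported isoform of each
    gene is always kept.
    """
    kept: List[TranscriptModel] = []
    for comp in _components(list(transcripts), min_gene_overlap_bp):
        total = sum(t.support for t in comp)
        top = max(comp, key=lambda t: (t.support, -t.start))
        for t in comp:
            if t is top or t.support >= min_isoform_fraction * total:
                kept.append(t)
    kept.sort(key=lambda t: (t.chrom, t.start, t.strand, tuple(t.blocks)))
    return kept


def cluster_genes(
    transcripts: Sequence[TranscriptModel],
    min_gene_overlap_bp: int = MIN_GENE_OVERLAP_BP,
) -> Tuple[List[GeneModel], List[TranscriptModel], List[FusionTranscript]]:
    """Cluster transcripts into genes and set aside fusion transcripts.

    A transcript is a fusion when removing it splits its overlap component
    into >=2 sub-components that each contain an HC (TSS- and PAS-anchored)
    transcript and that it overlaps; such bridging reads arise from
    inefficient termination across adjacent genes.  Returns (genes,
    transcripts-with-gene_id, fusions); fusions belong to no gene.
    """
    transcripts = list(transcripts)
    fusions_raw: List[TranscriptModel] = []
    for comp in _components(transcripts, min_gene_overlap_bp):
        if len(comp) < 3:
            continue
        for t in comp:
            rest = [x for x in comp if x is not t]
            subs = _components(rest, min_gene_overlap_bp)
            anchored = [
                sub
                for sub in subs
                if any(x.confidence == "HC" for x in sub)
                and any(_exonic_overlap(t, x, min_gene_overlap_bp) for x in sub)
            ]
            if len(anchored) >= 2:
                fusions_raw.append(t)

    fusion_ids = {id(t) for t in fusions_raw}
    remaining = [t for t in transcripts if id(t) not in fusion_ids]

    genes: List[GeneModel] = []
    comps = _components(remaining, min_gene_overlap_bp)
    comps.sort(key=lambda c: (c[0].chrom, min(t.start for t in c), c[0].strand))
    counters = {"HC": 0, "MC": 0, "LC": 0}
    for comp in comps:
        tier = max((t.confidence for t in comp), key=lambda c: TIER_ORDER[c])
        counters[tier] += 1
        gid = f"{tier}_gene_{counters[tier]:05d}"
        start = min(t.start for t in comp)
        end = max(t.end for t in comp)
        t_ids = []
        for k, t in enumerate(
            sorted(comp, key=lambda t: (-t.support, t.start, tuple(t.blocks))), start=1
        ):
            t.id = f"{gid}.{k}"
            t.gene_id = gid
            t_ids.append(t.id)
        genes.append(
            GeneModel(
                id=gid,
                interval=GenomicInterval(comp[0].chrom, start, end, comp[0].strand),
                confidence=tier,
                transcripts=t_ids,
            )
        )

    fusions: List[FusionTranscript] = []
    for k, t in enumerate(
        sorted(fusions_raw, key=lambda t: (t.chrom, t.start, tuple(t.blocks))), start=1
    ):
        spanned = [
            g.id
            for g in genes
            if g.interval.chrom == t.chrom
            and g.interval.strand == t.strand
            and g.interval.start < t.end
            and t.start < g.interval.end
        ]
        fusions.append(
            FusionTranscript(
                id=f"fusion_{k:05d}",
                chrom=t.chrom,
                strand=t.strand,
                blocks=t.blocks,
                support=t.support,
                spanned_gene_ids=spanned,
            )
        )
    return genes, remaining, fusions
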