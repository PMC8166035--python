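"""BAM ingestion for the four assay classes.

Long spliced reads become :class:`ReadAlignment` records (exon blocks split
at N CIGAR runs), 5'/3' tag libraries become sparse end-count profiles, and
nascent RNA-seq becomes strand-specific per-base coverage.  Replicate BAMs
are pooled.  All loaders drop secondary/supplementary alignments.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pysam

from .core import MIN_MAPQ, CoverageTrack, ReadAlignment, TagProfile

log = logging.getLogger(__name__)

_REF_CONSUMING = {0, 2, 7, 8}  # M, D, =, X extend the current block
_N_OP = 3  # N closes the block and opens a new one after the intron


def _open_bam(path: str) -> pysam.AlignmentFile:
    try:
        bam = pysam.AlignmentFile(str(path), "rb")
    except FileNotFoundError:
        raise FileNotFoundError(f"BAM not found: {path}")
    if not bam.has_index():
        raise ValueError(
            f"{path} has no index; run `samtools index` on the "
            "coordinate-sorted BAM first"
        )
    return bam


def blocks_from_cigar(pos: int, cigartuples: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Exonic blocks of a spliced alignment starting at reference ``pos``.

    M/=/X/D runs extend the current block (deletions do not split exons);
    only N opens a new block.  Soft/hard clips and insertions consume no
    reference and are ignored.
    """
    blocks: List[Tuple[int, int]] = []
    cur_start = pos
    cur = pos
    for op, length in cigartuples:
        if op in _REF_CONSUMING:
            cur += length
        elif op == _N_OP:
            if cur > cur_start:
                blocks.append((cur_start, cur))
            cur += length
            cur_start = cur
    if cur > cur_start:
        blocks.append((cur_start, cur))
    return blocks


def _keep(aln: pysam.AlignedSegment, min_mapq: int) -> bool:
    return not (
        aln.is_unmapped
        or aln.is_secondary
        or aln.is_supplementary
        or aln.mapping_quality < min_mapq
    )


def _strand(aln: pysam.AlignedSegment, reads_reverse_complemented: bool) -> str:
    s = "-" if aln.is_reverse else "+"
    if reads_reverse_complemented:
        s = "-" if s == "+" else "+"
    return s


def load_long_reads(
    bam_path: str,
    min_mapq: int = MIN_MAPQ,
    reads_reverse_complemented: bool = False,
) -> List[ReadAlignment]:
    """Parse primary spliced long-read alignments into ReadAlignments."""
    reads: List[ReadAlignment] = []
    n_total = 0
    with _open_bam(bam_path) as bam:
        for aln in bam.fetch():
            n_total += 1
            if not _keep(aln, min_mapq):
                continue
            blocks = blocks_from_cigar(aln.reference_start, aln.cigartuples or [])
            if not blocks:
                continue
            read = ReadAlignment(
                read_id=aln.query_name,
                chrom=aln.reference_name,
                strand=_strand(aln, reads_reverse_complemented),
                blocks=blocks,
            )
            read.validate()
            reads.append(read)
    if n_total == 0:
        log.warning("%s contains no mapped alignments", bam_path)
    return reads


def load_tag_profile(bam_paths: Sequence[str], mode: str) -> TagProfile:
    """Pool replicate tag BAMs into per-(chrom, strand) end counts.

    TSS mode counts the 5'-most aligned base of each read on its strand;
    PAS mode counts the 3'-most base.
    """
    if mode not in ("TSS", "PAS"):
        raise ValueError(f"mode must be 'TSS' or 'PAS', got {mode!r}")
    profile: TagProfile = {}
    total = 0
    for path in bam_paths:
        with _open_bam(path) as bam:
            for aln in bam.fetch():
                if not _keep(aln, 0):
                    continue
                strand = "-" if aln.is_reverse else "+"
                if (mode == "TSS") == (strand == "+"):
                    pos = aln.reference_start
                else:
                    pos = aln.reference_end - 1
                key = (aln.reference_name, strand)
                counts = profile.setdefault(key, {})
                counts[pos] = counts.get(pos, 0) + 1
                total += 1
    if total == 0:
        raise ValueError(
            f"no usable {mode} tag reads in {list(bam_paths)}; the pipeline "
            "cannot classify long reads without tag data"
        )
    return profile


def load_nascent_coverage(bam_paths: Sequence[str]) -> CoverageTrack:
    """Strand-specific per-base depth over exonic blocks, replicates pooled."""
    sizes: Dict[str, int] = {}
    track: CoverageTrack = {}
    any_read = False
    for path in bam_paths:
        with _open_bam(path) as bam:
            for name, length in zip(bam.references, bam.lengths):
                sizes[name] = max(sizes.get(name, 0), length)
            for aln in bam.fetch():
                if not _keep(aln, 0):
                    continue
                any_read = True
                strand = "-" if aln.is_reverse else "+"
                key = (aln.reference_name, strand)
                if key not in track:
                    track[key] = np.zeros(sizes[aln.reference_name], dtype=np.int32)
                depth = track[key]
                for s, e in blocks_from_cigar(aln.reference_start, aln.cigartuples or []):
                    depth[s:e] += 1
    if not any_read:
        log.warning("nascent BAMs %s contain no usable reads", list(bam_paths))
    # guarantee an array for every (chrom, strand) seen in any header
    for name, length in sizes.items():
        for strand in ("+", "-"):
            track.setdefault((name, strand), np.zeros(length, dtype=np.int32))
    return track


def total_tag_count(profile: TagProfile) -> int:
    return sum(sum(counts.values()) for counts in profile.values())
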