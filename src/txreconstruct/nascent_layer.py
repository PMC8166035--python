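"""Nascent-transcription layer.

Continuous intervals of nascent coverage typically blanket a larger part of
the genome than mature-RNA gene models.  Intervals (or parts of intervals)
beyond a gene's 3' border become read-through (RT) tails appended to the
gene — the torpedo-model continuation of RNAPII past the PAS — while
intervals with no same-strand overlap to any called gene become transient
RNAs (unstable and/or non-polyadenylated species invisible to poly(A)-
dependent assays).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    LINK_DISTANCE,
    MIN_INTERVAL_LENGTH,
    MIN_TAIL,
    NASCENT_MAX_GAP,
    NASCENT_MIN_DEPTH,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    NascentInterval,
    TransientRNA,
)


def call_nascent_intervals(
    track: CoverageTrack,
    min_depth: int = NASCENT_MIN_DEPTH,
    max_gap: int = NASCENT_MAX_GAP,
    min_interval_length: int = MIN_INTERVAL_LENGTH,
) -> List[NascentInterval]:
    """Maximal runs with depth >= min_depth, bridging gaps <= max_gap,
    dropping islands shorter than min_interval_length."""
    out: List[NascentInterval] = []
    for (chrom, strand) in sorted(track):
        depth = np.asarray(track[(chrom, strand)])
        mask = depth >= min_depth
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        breaks = np.flatnonzero(np.diff(idx) > max_gap + 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(idx) - 1]))
        for a, b in zip(starts, ends):
            s, e = int(idx[a]), int(idx[b]) + 1
            if e - s < min_interval_length:
                continue
            out.append(
                NascentInterval(
                    interval=GenomicInterval(chrom, s, e, strand),
                    mean_depth=float(depth[s:e].mean()),
                )
            )
    return out


def append_rt_tails(
    genes: Sequence[GeneModel],
    intervals: Sequence[NascentInterval],
    link_distance: int = LINK_DISTANCE,
    min_tail: int = MIN_TAIL,
) -> List[NascentInterval]:
    """Assign read-through tails to genes and classify interval pieces.

    The gene-overhanging part of a nascent interval whose 5' end lies
    within ``link_distance`` downstream of a gene's 3' border (same strand)
    becomes that gene's RT tail; ``gene.rt_tail`` is the overhang length,
    truncated at the 5' border of the next same-strand gene.  Tails shorter
    than ``min_tail`` are recorded on the gene but reported below-threshold.
    Returns the classified pieces (within_gene / rt_tail / unassigned)
    partitioning the input intervals.
    """
    by_key: Dict[Tuple[str, str], List[GeneModel]] = {}
    for g in genes:
        by_key.setdefault((g.interval.chrom, g.strand), []).append(g)
    for key in by_key:
        by_key[key].sort(key=lambda g: g.interval.start)

    pieces: List[NascentInterval] = []
    for iv in intervals:
        chrom, strand = iv.interval.chrom, iv.interval.strand
        loc_genes = by_key.get((chrom, strand), [])
        segments = _split_by_genes(iv, loc_genes)
        pieces.extend(segments)

    # RT assignment: for each gene, the unassigned piece nearest downstream
    for key, loc_genes in sorted(by_key.items()):
        for gi, g in enumerate(loc_genes):
            if g.strand == "+":
                end3 = g.interval.end
                nxt = loc_genes[gi + 1].interval.start if gi + 1 < len(loc_genes) else None
            else:
                end3 = g.interval.start
                nxt = loc_genes[gi - 1].interval.end if gi > 0 else None
            best: Optional[NascentInterval] = None
            for p in pieces:
                if p.classification != "unassigned":
                    continue
                if p.interval.chrom != key[0] or p.interval.strand != key[1]:
                    continue
                if g.strand == "+":
                    head = p.interval.start
                    if end3 <= head <= end3 + link_distance or (
                        head < end3 < p.interval.end
                    ):
                        if best is None or p.interval.start < best.interval.start:
                            best = p
                else:
                    head = p.interval.end
                    if end3 - link_distance <= head <= end3 or (
                        p.interval.start < end3 < p.interval.end
                    ):
                        if best is None or p.interval.end > best.interval.end:
                            best = p
            if best is None:
                continue
            if g.strand == "+":
                tail_start = max(best.interval.start, end3)
                tail_end = best.interval.end if nxt is None else min(best.interval.end, nxt)
            else:
                tail_end = min(best.interval.end, end3)
                tail_start = best.interval.start if nxt is None else max(best.interval.start, nxt)
            length = max(0, tail_end - tail_start)
            if length <= 0:
                continue
            best.classification = "rt_tail"
            best.gene_id = g.id
            best.interval = GenomicInterval(key[0], tail_start, tail_end, key[1])
            g.rt_tail = length
    return pieces


def _split_by_genes(
    iv: NascentInterval, loc_genes: Sequence[GeneModel]
) -> List[NascentInterval]:
    """Cut an interval at same-strand gene overlaps.

    Overlapping parts are classified within_gene; the remainder stays
    unassigned for RT-tail / transient classification."""
    chrom, strand = iv.interval.chrom, iv.interval.strand
    cuts: List[Tuple[int, int, Optional[str]]] = []
    pos = iv.interval.start
    end = iv.interval.end
    for g in loc_genes:
        gs, ge = g.interval.start, g.interval.end
        if ge <= pos or gs >= end:
            continue
        if gs > pos:
            cuts.append((pos, gs, None))
        cuts.append((max(pos, gs), min(end, ge), g.id))
        pos = min(end, ge)
        if pos >= end:
            break
    if pos < end:
        cuts.append((pos, end, None))
    out = []
    for s, e, gid in cuts:
        if e <= s:
            continue
        out.append(
            NascentInterval(
                interval=GenomicInterval(chrom, s, e, strand),
                mean_depth=iv.mean_depth,
                classification="within_gene" if gid else "unassigned",
                gene_id=gid,
            )
        )
    return out


def call_transient_rnas(
    pieces: Sequence[NascentInterval],
    genes: Sequence[GeneModel],
    min_interval_length: int = MIN_INTERVAL_LENGTH,
) -> List[TransientRNA]:
    """Remaining pieces with no same-strand gene overlap become transient RNAs."""
    out: List[TransientRNA] = []
    k = 0
    for p in sorted(
        pieces, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.strand)
    ):
        if p.classification != "unassigned":
            continue
        if len(p.interval) < min_interval_length:
            continue
        p.classification = "transient"
        k += 1
        out.append(TransientRNA(id=f"transient_{k:05d}", interval=p.interval))
    return out


def classify_orientation(
    units: Sequence, reference: Optional[Sequence[GenomicInterval]]
) -> None:
    """Label units antisense (opposite-strand overlap with a reference gene)
    or intergenic; 'unclassified' when no reference is given.

    Works on any object with ``interval`` and ``orientation_class``
    attributes (TransientRNA) or GeneModels via their interval.
    """
    for u in units:
        iv: GenomicInterval = u.interval
        if reference is None:
            u.orientation_class = "unclassified"
            continue
        antisense = any(
            r.chrom == iv.chrom
            and r.strand != iv.strand
            and r.start < iv.end
            and iv.start < r.end
            for r in reference
        )
        u.orientation_class = "antisense" if antisense else "intergenic"
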