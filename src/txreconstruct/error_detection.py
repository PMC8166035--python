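"""Under-splitting error detection.

Long-read aligners sometimes extend an exon across its intron, so the next
exon appears missing from the read.  Assuming the majority of reads at a
locus align correctly, each read is compared to the chain of constitutive
exons of its TSS-PAS group: a subalignment with a deviant border is a valid
alternative exon only when the read's next subalignment exactly matches the
next constitutive exon; otherwise the read is flagged and excluded from
transcript calling.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .core import CONSTITUTIVE_FRACTION, ReadAlignment

Block = Tuple[int, int]


@dataclass
class ReadGroup:
    """Complete reads sharing one (tss_id, pas_id) key."""

    key: Tuple[str, str]
    chrom: str
    strand: str
    members: List[ReadAlignment] = field(default_factory=list)
    constitutive_exons: List[Block] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(r.start for r in self.members)

    @property
    def end(self) -> int:
        return max(r.end for r in self.members)


def group_reads(reads: Sequence[ReadAlignment]) -> List[ReadGroup]:
    """One group per distinct (tss_id, pas_id) pair among complete reads."""
    groups: Dict[Tuple[str, str], ReadGroup] = {}
    for r in reads:
        if r.tss_id is None or r.pas_id is None:
            continue
        key = (r.tss_id, r.pas_id)
        g = groups.get(key)
        if g is None:
            g = groups[key] = ReadGroup(key=key, chrom=r.chrom, strand=r.strand)
        g.members.append(r)
    out = sorted(groups.values(), key=lambda g: (g.chrom, g.start, g.strand, g.key))
    return out


def call_constitutive_exons(
    group: ReadGroup, constitutive_fraction: float = CONSTITUTIVE_FRACTION
) -> List[Block]:
    """Exons present in strictly more than ``constitutive_fraction`` of the
    group's reads (exact unified coordinates), sorted genomically.

    In a singleton group every exon trivially exceeds the 50% majority.
    Should two constitutive candidates overlap (possible only across exon
    variants in small groups), the more frequent one wins, ties leftmost.
    """
    n = len(group.members)
    if n == 0:
        raise ValueError("empty read group")
    counts: Counter = Counter()
    for r in group.members:
        for b in r.blocks:
            counts[b] += 1
    candidates = sorted(
        (b for b, c in counts.items() if c > constitutive_fraction * n),
        key=lambda b: (-counts[b], b),
    )
    chosen: List[Block] = []
    for b in candidates:
        if all(b[1] <= c[0] or c[1] <= b[0] for c in chosen):
            chosen.append(b)
    chosen.sort()
    group.constitutive_exons = chosen
    return chosen


def flag_alignment_errors(read: ReadAlignment, constitutive: Sequence[Block]) -> ReadAlignment:
    """Set ``error_flag`` if the read shows an under-splitting signature.

    Walk subalignments 5'->3'.  An exact match to a constitutive exon always
    passes.  A deviant subalignment is tolerated only if the read's next
    subalignment exactly equals the constitutive exon following the first
    one it overlaps (or following its position, when it overlaps none); with
    no next constitutive exon the deviation is terminal and never flagged.
    Coordinates are never modified.
    """
    if not constitutive:
        return read
    forward = read.strand == "+"
    blocks = list(read.blocks) if forward else list(reversed(read.blocks))
    chain = list(constitutive) if forward else list(reversed(constitutive))

    def is_after(c: Block, b: Block) -> bool:
        # c strictly downstream (5'->3') of b
        return c[0] >= b[1] if forward else c[1] <= b[0]

    const_set = set(chain)
    for i, b in enumerate(blocks):
        if b in const_set:
            continue
        overlapped = [k for k, c in enumerate(chain) if c[0] < b[1] and b[0] < c[1]]
        if overlapped:
            nxt = overlapped[0] + 1
            next_c = chain[nxt] if nxt < len(chain) else None
        else:
            next_c = next((c for c in chain if is_after(c, b)), None)
        if next_c is None:
            continue  # deviation at the far terminus: nothing left to miss
        if i + 1 < len(blocks) and blocks[i + 1] == next_c:
            continue  # novel alternative exon, resynchronized
        read.error_flag = True
        return read
    return read


def flag_all(
    reads: Sequence[ReadAlignment],
    constitutive_fraction: float = CONSTITUTIVE_FRACTION,
) -> Tuple[List[ReadGroup], float]:
    """Group complete reads, call constitutive exons, and flag every read.

    Incomplete reads (missing a TSS-PAS key) are checked against the
    constitutive chain of the single read group their span overlaps, if
    exactly one exists; otherwise they pass unflagged.  Returns the groups
    and the flagged-read fraction over all reads.
    """
    groups = group_reads(reads)
    for g in groups:
        call_constitutive_exons(g, constitutive_fraction)
        for r in g.members:
            flag_alignment_errors(r, g.constitutive_exons)

    keyed = {id(r) for g in groups for r in g.members}
    by_loc: Dict[Tuple[str, str], List[ReadGroup]] = {}
    for g in groups:
        by_loc.setdefault((g.chrom, g.strand), []).append(g)
    n_flagged = 0
    for r in reads:
        if id(r) not in keyed:
            overlapping = [
                g
                for g in by_loc.get((r.chrom, r.strand), [])
                if g.start < r.end and r.start < g.end
            ]
            if len(overlapping) == 1:
                flag_alignment_errors(r, overlapping[0].constitutive_exons)
        if r.error_flag:
            n_flagged += 1
    frac = n_flagged / len(reads) if reads else 0.0
    return groups, frac
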