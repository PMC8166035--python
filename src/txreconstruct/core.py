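"""Core domain types shared by every pipeline stage.

All coordinates are 0-based half-open genomic intervals, the native
arithmetic of BAM and BED.  GFF3 output converts on the fly.  Strand is
always one of ``+``/``-``; unstranded records are rejected at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

# Pipeline defaults.  The extension limit (100 bp), border offset (10 bp),
# constitutive-exon majority (>50%), minor-isoform floor (<1%) and the
# 50 bp RT-tail reporting threshold are the published defaults of the
# method; the remaining values are this implementation's own defaults for
# steps the method leaves parameterized (all CLI-exposed).
MAX_EXTENSION = 100
MAX_BORDER_OFFSET = 10
CONSTITUTIVE_FRACTION = 0.5
MIN_ISOFORM_FRACTION = 0.01
MIN_TAIL = 50
TAG_MAX_GAP = 25
TAG_MIN_COUNT = 3
NASCENT_MIN_DEPTH = 1
NASCENT_MAX_GAP = 100
MIN_INTERVAL_LENGTH = 50
LINK_DISTANCE = 100
MIN_GENE_OVERLAP_BP = 1
MIN_MAPQ = 1

STRANDS = ("+", "-")


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A strand-aware span: 0-based inclusive start, exclusive end."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", same_strand: bool = True) -> bool:
        if self.chrom != other.chrom:
            return False
        if same_strand and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def jaccard(self, other: "GenomicInterval") -> float:
        inter = self.overlap_len(other)
        if inter == 0:
            return 0.0
        union = max(self.end, other.end) - min(self.start, other.start)
        return inter / union


Block = Tuple[int, int]


def check_blocks(blocks: List[Block]) -> None:
    """Blocks must be strictly increasing and non-overlapping."""
    for (s, e) in blocks:
        if not 0 <= s < e:
            raise ValueError(f"invalid block [{s}, {e})")
    for (_, e1), (s2, _) in zip(blocks, blocks[1:]):
        if s2 < e1:
            raise ValueError("blocks overlap or are out of order")


@dataclass(slots=True)
class ReadAlignment:
    """A spliced long read as an ordered run of exonic blocks.

    ``blocks`` are (start, end) pairs on one chrom/strand in genomic order;
    gaps between consecutive blocks are introns.  Support flags and the
    error flag are filled in by later stages.
    """

    read_id: str
    chrom: str
    strand: str
    blocks: List[Block]
    tss_supported: bool = False
    pas_supported: bool = False
    extended_5p: int = 0
    extended_3p: int = 0
    error_flag: bool = False
    tss_id: Optional[str] = None
    pas_id: Optional[str] = None

    def validate(self) -> None:
        check_blocks(self.blocks)

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    def five_prime(self) -> int:
        """Genomic position of the 5' terminal base."""
        return self.start if self.strand == "+" else self.end - 1

    def three_prime(self) -> int:
        """Genomic position of the 3' terminal base."""
        return self.end - 1 if self.strand == "+" else self.start

    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    def block_key(self) -> Tuple:
        return (self.chrom, self.strand, tuple(self.blocks))


# TagProfile: per (chrom, strand) sparse map of position -> tag-end count.
TagProfile = Dict[Tuple[str, str], Dict[int, int]]

# CoverageTrack: per (chrom, strand) dense per-base depth (numpy int array).
CoverageTrack = Dict[Tuple[str, str], "object"]


@dataclass(slots=True)
class TagCluster:
    """A called TSS or PAS: an interval with a summit and a tag score."""

    id: str
    interval: GenomicInterval
    summit: int
    score: int
    kind: str  # "TSS" | "PAS"

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit outside cluster interval")
        if self.kind not in ("TSS", "PAS"):
            raise ValueError(f"kind must be TSS or PAS, got {self.kind!r}")


@dataclass(slots=True)
class TranscriptModel:
    id: str
    chrom: str
    strand: str
    blocks: List[Block]
    confidence: str  # "HC" | "MC" | "LC"
    support: int
    tss_id: Optional[str] = None
    pas_id: Optional[str] = None
    gene_id: Optional[str] = None

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass(slots=True)
class GeneModel:
    id: str
    interval: GenomicInterval
    confidence: str
    transcripts: List[str]
    rt_tail: int = 0

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(slots=True)
class FusionTranscript:
    id: str
    chrom: str
    strand: str
    blocks: List[Block]
    support: int
    spanned_gene_ids: List[str] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]


@dataclass(slots=True)
class NascentInterval:
    interval: GenomicInterval
    mean_depth: float
    classification: str = "unassigned"  # within_gene | rt_tail | transient
    gene_id: Optional[str] = None


@dataclass(slots=True)
class TransientRNA:
    id: str
    interval: GenomicInterval
    orientation_class: str = "unclassified"  # antisense | intergenic | unclassified


TIER_ORDER = {"HC": 3, "MC": 2, "LC": 1}


def tier_of(tss_id: Optional[str], pas_id: Optional[str]) -> str:
    if tss_id is not None and pas_id is not None:
        return "HC"
    if tss_id is not None or pas_id is not None:
        return "MC"
    return "LC"
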