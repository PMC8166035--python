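"""Synthetic ground truth and matched BAM generation for all four assays.

The generator emulates the noise modes of the real inputs: 3'-anchored
long reads whose 5' ends start a few tens of bases downstream of the true
TSS (or, with probability ``truncation_rate``, anywhere inside the
transcript), small zero-mean jitter at splice borders, under-splitting
(an intron erased so adjacent exons merge), tag pileups dispersed around
the true TSS/PAS plus sparse singleton background tags, and nascent
coverage tiling gene bodies, read-through tails and gene-free transient
units.  Everything is written as valid sorted, indexed BAM against a
synthetic FASTA, and the ground truth is serialized as JSON + BED12.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .core import GenomicInterval, GeneModel, TranscriptModel, TransientRNA
from .bedio import bed12_line

Block = Tuple[int, int]

TAG_READ_LEN = 30
NASCENT_READ_LEN = 50
MIN_KEEP = 50  # shortest simulated 3' suffix after truncation
JITTER_CAP = 9  # keeps noise inside the 10 bp unification radius
TAG_JITTER_CAP = 5


@dataclass
class SimIsoform:
    exons: List[Block]
    abundance: float


@dataclass
class SimGene:
    name: str
    chrom: str
    strand: str
    isoforms: List[SimIsoform]
    rt_tail: int = 0
    readthrough_into: Optional[str] = None
    readthrough_rate: float = 0.0

    @property
    def start(self) -> int:
        return min(i.exons[0][0] for i in self.isoforms)

    @property
    def end(self) -> int:
        return max(i.exons[-1][1] for i in self.isoforms)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def pas_sites(self) -> Dict[int, float]:
        """Distinct PAS positions with summed isoform abundance."""
        sites: Dict[int, float] = {}
        for iso in self.isoforms:
            p = iso.exons[-1][1] - 1 if self.strand == "+" else iso.exons[0][0]
            sites[p] = sites.get(p, 0.0) + iso.abundance
        return sites


@dataclass
class GroundTruth:
    chrom_sizes: Dict[str, int]
    genes: List[SimGene]
    transients: List[GenomicInterval]
    truncation_rate: float = 0.4
    border_jitter_sd: float = 2.0
    undersplit_rate: float = 0.05
    tag_jitter_sd: float = 1.8
    tags_per_site: int = 60
    noise_tags_per_chrom: int = 30
    nascent_depth: float = 5.0

    def validate(self) -> None:
        problems: List[str] = []
        for rate in (self.truncation_rate, self.undersplit_rate):
            if not 0.0 <= rate <= 1.0:
                problems.append(f"rate {rate} outside [0, 1]")
        for g in self.genes:
            total = sum(i.abundance for i in g.isoforms)
            if abs(total - 1.0) > 1e-9:
                problems.append(f"{g.name}: isoform abundances sum to {total}")
            for iso in g.isoforms:
                for s, e in iso.exons:
                    if not 0 <= s < e <= self.chrom_sizes[g.chrom]:
                        problems.append(f"{g.name}: exon [{s},{e}) out of bounds")
                for (_, e1), (s2, _) in zip(iso.exons, iso.exons[1:]):
                    if s2 <= e1:
                        problems.append(f"{g.name}: exons unordered")
        if problems:
            raise ValueError("inconsistent ground truth: " + "; ".join(problems))

    def isoform_table(self) -> List[Tuple[str, str, str, List[Block], float]]:
        """(gene, chrom, strand, exons, abundance) per isoform."""
        return [
            (g.name, g.chrom, g.strand, iso.exons, iso.abundance)
            for g in self.genes
            for iso in g.isoforms
        ]


@dataclass
class SimPaths:
    out_dir: str
    fasta: str
    long_bam: str
    tss_bams: List[str]
    pas_bams: List[str]
    nascent_bams: List[str]
    truth_json: str
    truth_bed: str


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def default_truth() -> GroundTruth:
    """Ten genes on two small chromosomes.

    Includes one convergent overlapping pair (g04-/g05+), one closely
    spaced same-strand pair with read-through into the downstream gene
    (g02+ -> g03+, exercising fusion calling and RT-tail truncation), a
    two-PAS gene (g07), an intronless gene (g08) and a sub-1%-abundance
    minor isoform (g10) that the 1% filter is expected to miss.
    """
    genes = [
        SimGene("g01", "chr1", "+", [
            SimIsoform([(2000, 2350), (2550, 2800), (3000, 3400)], 0.7),
            SimIsoform([(2000, 2350), (3000, 3400)], 0.3),
        ], rt_tail=350),
        SimGene("g02", "chr1", "+", [
            SimIsoform([(6000, 6400), (6600, 7000), (7200, 7600)], 1.0),
        ], rt_tail=180, readthrough_into="g03", readthrough_rate=0.05),
        SimGene("g03", "chr1", "+", [
            SimIsoform([(7900, 8300), (8500, 8900)], 1.0),
        ], rt_tail=300),
        SimGene("g05", "chr1", "+", [
            SimIsoform([(12000, 12500), (12700, 13200)], 1.0),
        ], rt_tail=150),
        SimGene("g04", "chr1", "-", [
            SimIsoform([(13000, 13600), (13800, 14200)], 1.0),
        ], rt_tail=200),
        SimGene("g06", "chr1", "-", [
            SimIsoform([(20000, 20500), (20700, 21100), (21300, 21800)], 0.75),
            SimIsoform([(20000, 20500), (21300, 21800)], 0.25),
        ], rt_tail=250),
        SimGene("g07", "chr2", "+", [
            SimIsoform([(5000, 5400), (5600, 6000)], 0.6),
            SimIsoform([(5000, 5400), (5600, 6800)], 0.4),
        ], rt_tail=250),
        SimGene("g08", "chr2", "+", [
            SimIsoform([(10000, 11800)], 1.0),
        ], rt_tail=400),
        SimGene("g09", "chr2", "-", [
            SimIsoform([(16000, 16450), (16650, 17100), (17300, 17800)], 0.7),
            SimIsoform([(16000, 16450), (17300, 17800)], 0.3),
        ], rt_tail=300),
        SimGene("g10", "chr2", "-", [
            SimIsoform([(22000, 22400), (22600, 23000), (23200, 23600), (23800, 24200)], 0.592),
            SimIsoform([(22000, 22400), (22600, 23000), (23800, 24200)], 0.4),
            SimIsoform([(22000, 22400), (23800, 24200)], 0.008),
        ], rt_tail=0),
    ]
    transients = [
        GenomicInterval("chr1", 30000, 30500, "+"),
        GenomicInterval("chr1", 12100, 12600, "-"),
        GenomicInterval("chr1", 40000, 40800, "-"),
        GenomicInterval("chr2", 30000, 30400, "+"),
        GenomicInterval("chr2", 16100, 16500, "+"),
    ]
    truth = GroundTruth(
        chrom_sizes={"chr1": 100_000, "chr2": 60_000},
        genes=genes,
        transients=transients,
    )
    truth.validate()
    return truth


def calibration_truth(undersplit_rate: float) -> GroundTruth:
    """Five well-separated multi-exon single-isoform genes, truncation off.

    Isolates the under-splitting detector: every simulated read is complete
    and eligible, so the flagged fraction estimates the injected rate."""
    genes = []
    for k in range(5):
        base = 5000 + k * 8000
        strand = "+" if k % 2 == 0 else "-"
        exons = [
            (base, base + 300),
            (base + 500, base + 800),
            (base + 1000, base + 1300),
            (base + 1500, base + 1900),
        ]
        genes.append(
            SimGene(f"c{k + 1:02d}", "chr1", strand, [SimIsoform(exons, 1.0)])
        )
    truth = GroundTruth(
        chrom_sizes={"chr1": 50_000},
        genes=genes,
        transients=[],
        truncation_rate=0.0,
        border_jitter_sd=2.0,
        undersplit_rate=undersplit_rate,
        nascent_depth=0.0,
    )
    truth.validate()
    return truth


def stress_truth() -> GroundTruth:
    """Default conditions but border jitter beyond the unification radius
    (documented failure mode of majority-vote denoising)."""
    truth = default_truth()
    truth.border_jitter_sd = 8.0
    return truth


PRESETS = {
    "default": default_truth,
    "stress": stress_truth,
}


# ---------------------------------------------------------------------------
# Read synthesis
# ---------------------------------------------------------------------------


def _trim_5p(blocks: List[Block], strand: str, cut: int) -> List[Block]:
    """Remove ``cut`` transcript bases from the 5' end of the block chain."""
    if cut <= 0:
        return list(blocks)
    out: List[Block] = []
    remaining = cut
    for s, e in blocks if strand == "+" else reversed(blocks):
        size = e - s
        if remaining >= size:
            remaining -= size
            continue
        if remaining > 0:
            out.append((s + remaining, e) if strand == "+" else (s, e - remaining))
            remaining = 0
        else:
            out.append((s, e))
    return out if strand == "+" else list(reversed(out))


def _jitter(rng: np.random.Generator, sd: float) -> int:
    """Zero-mean border noise: exact with probability 1/2, else a rounded
    Gaussian rescaled so the overall standard deviation equals ``sd``."""
    if sd <= 0 or rng.random() < 0.5:
        return 0
    d = int(round(rng.normal(0.0, sd * math.sqrt(2.0))))
    return max(-JITTER_CAP, min(JITTER_CAP, d))


def _jitter_internal_borders(
    blocks: List[Block], rng: np.random.Generator, sd: float
) -> List[Block]:
    out = [list(b) for b in blocks]
    for i in range(len(out) - 1):
        out[i][1] += _jitter(rng, sd)  # donor side
        out[i + 1][0] += _jitter(rng, sd)  # acceptor side
    fixed = [(int(s), int(e)) for s, e in out]
    for (s, e) in fixed:
        if s >= e:
            return list(blocks)  # degenerate jitter, keep the clean read
    for (_, e1), (s2, _) in zip(fixed, fixed[1:]):
        if s2 <= e1:
            return list(blocks)
    return fixed


def _simulate_long_reads(
    truth: GroundTruth, depth: int, rng: np.random.Generator
) -> List[Tuple[str, str, str, List[Block]]]:
    """(read_id, chrom, strand, blocks) per read; exactly ``depth`` per gene."""
    by_name = {g.name: g for g in truth.genes}
    reads = []
    for g in truth.genes:
        probs = np.array([i.abundance for i in g.isoforms])
        choices = rng.choice(len(g.isoforms), size=depth, p=probs / probs.sum())
        for k in range(depth):
            if g.readthrough_into and rng.random() < g.readthrough_rate:
                partner = by_name[g.readthrough_into]
                if g.strand == "+":
                    up, down = g.isoforms[0].exons, partner.isoforms[0].exons
                    blocks = up[:-1] + [(up[-1][0], down[0][1])] + down[1:]
                else:
                    up, down = partner.isoforms[0].exons, g.isoforms[0].exons
                    blocks = up[:-1] + [(up[-1][0], down[0][1])] + down[1:]
            else:
                blocks = list(g.isoforms[int(choices[k])].exons)
            tlen = sum(e - s for s, e in blocks)
            if rng.random() < truth.truncation_rate:
                cut = int(rng.integers(0, max(1, tlen - MIN_KEEP)))
            else:
                cut = int(rng.integers(6, 41))  # a few tens of nt downstream
            blocks = _trim_5p(blocks, g.strand, cut)
            blocks = _jitter_internal_borders(blocks, rng, truth.border_jitter_sd)
            if len(blocks) >= 2 and rng.random() < truth.undersplit_rate:
                j = int(rng.integers(0, len(blocks) - 1))
                blocks = blocks[:j] + [(blocks[j][0], blocks[j + 1][1])] + blocks[j + 2:]
            reads.append((f"{g.name}_r{k:05d}", g.chrom, g.strand, blocks))
    return reads


def _tag_positions(
    truth: GroundTruth, rng: np.random.Generator, kind: str
) -> List[Tuple[str, str, int]]:
    """(chrom, strand, position) of every simulated tag 5'/3' end."""
    tags: List[Tuple[str, str, int]] = []
    for g in truth.genes:
        if kind == "TSS":
            sites = {g.tss: 1.0}
        else:
            sites = g.pas_sites()
        for pos, weight in sorted(sites.items()):
            n = max(5, int(round(truth.tags_per_site * weight)))
            for _ in range(n):
                # dominant exact position with surrounding dispersion, as in
                # real 5'/3' tag pileups
                if rng.random() < 0.5:
                    d = 0
                else:
                    d = int(round(rng.normal(0.0, truth.tag_jitter_sd * math.sqrt(2.0))))
                    d = max(-TAG_JITTER_CAP, min(TAG_JITTER_CAP, d))
                tags.append((g.chrom, g.strand, pos + d))
    for chrom, size in sorted(truth.chrom_sizes.items()):
        for _ in range(truth.noise_tags_per_chrom):
            strand = "+" if rng.random() < 0.5 else "-"
            tags.append((chrom, strand, int(rng.integers(100, size - 100))))
    return tags


def _nascent_regions(truth: GroundTruth) -> List[Tuple[str, str, int, int]]:
    regions = []
    for g in truth.genes:
        if g.strand == "+":
            regions.append((g.chrom, "+", g.start, g.end + g.rt_tail))
        else:
            regions.append((g.chrom, "-", g.start - g.rt_tail, g.end))
    for t in truth.transients:
        regions.append((t.chrom, t.strand, t.start, t.end))
    return regions


# ---------------------------------------------------------------------------
# BAM / FASTA plumbing
# ---------------------------------------------------------------------------


def _write_bam(path: str, header: dict, records: List[pysam.AlignedSegment]) -> None:
    tmp = path + ".unsorted.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as bam:
        for rec in records:
            bam.write(rec)
    pysam.sort("-o", path, tmp)
    os.remove(tmp)
    pysam.index(path)


def _segment(
    header: pysam.AlignmentHeader,
    name: str,
    chrom: str,
    strand: str,
    blocks: Sequence[Block],
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.flag = 16 if strand == "-" else 0
    a.reference_id = header.get_tid(chrom)
    a.reference_start = blocks[0][0]
    a.mapping_quality = 60
    cigar = []
    prev_end = None
    for s, e in blocks:
        if prev_end is not None:
            cigar.append((3, s - prev_end))  # N
        cigar.append((0, e - s))  # M
        prev_end = e
    a.cigartuples = cigar
    return a


def simulate_dataset(
    truth: GroundTruth,
    depth: int,
    seed: int,
    out_dir: str,
    tag_replicates: int = 2,
) -> SimPaths:
    """Write the four assay BAM sets plus FASTA and serialized truth."""
    truth.validate()
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    names = sorted(truth.chrom_sizes)
    header_dict = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": truth.chrom_sizes[n]} for n in names],
    }
    header = pysam.AlignmentHeader.from_dict(header_dict)

    fasta = os.path.join(out_dir, "genome.fa")
    _write_fasta(fasta, truth.chrom_sizes, rng)

    # long reads
    long_bam = os.path.join(out_dir, "long_reads.bam")
    records = [
        _segment(header, rid, chrom, strand, blocks)
        for rid, chrom, strand, blocks in _simulate_long_reads(truth, depth, rng)
    ]
    _write_bam(long_bam, header_dict, records)

    # tag libraries, split across replicates
    tss_bams, pas_bams = [], []
    for kind, store in (("TSS", tss_bams), ("PAS", pas_bams)):
        tags = _tag_positions(truth, rng, kind)
        reps: List[List[pysam.AlignedSegment]] = [[] for _ in range(tag_replicates)]
        for i, (chrom, strand, pos) in enumerate(tags):
            if kind == "TSS":
                block = (pos, pos + TAG_READ_LEN) if strand == "+" else (pos - TAG_READ_LEN + 1, pos + 1)
            else:
                block = (pos - TAG_READ_LEN + 1, pos + 1) if strand == "+" else (pos, pos + TAG_READ_LEN)
            seg = _segment(header, f"{kind}_t{i:06d}", chrom, strand, [block])
            reps[i % tag_replicates].append(seg)
        for r, recs in enumerate(reps, start=1):
            path = os.path.join(out_dir, f"{kind.lower()}_rep{r}.bam")
            _write_bam(path, header_dict, recs)
            store.append(path)

    # nascent coverage
    nascent_bams = []
    if truth.nascent_depth > 0:
        recs = []
        i = 0
        for chrom, strand, start, end in _nascent_regions(truth):
            span = end - start
            n = int(math.ceil(truth.nascent_depth * span / NASCENT_READ_LEN))
            for _ in range(n):
                s = int(rng.integers(start, max(start + 1, end - NASCENT_READ_LEN)))
                recs.append(
                    _segment(header, f"nas_{i:06d}", chrom, strand, [(s, s + NASCENT_READ_LEN)])
                )
                i += 1
        path = os.path.join(out_dir, "nascent.bam")
        _write_bam(path, header_dict, recs)
        nascent_bams.append(path)

    truth_json = os.path.join(out_dir, "truth.json")
    truth_bed = os.path.join(out_dir, "truth_isoforms.bed")
    _serialize_truth(truth, truth_json, truth_bed)
    return SimPaths(
        out_dir=out_dir,
        fasta=fasta,
        long_bam=long_bam,
        tss_bams=tss_bams,
        pas_bams=pas_bams,
        nascent_bams=nascent_bams,
        truth_json=truth_json,
        truth_bed=truth_bed,
    )


def _write_fasta(path: str, chrom_sizes: Dict[str, int], rng: np.random.Generator) -> None:
    bases = np.frombuffer(b"ACGT", dtype="S1")
    with open(path, "w") as fh:
        for name in sorted(chrom_sizes):
            fh.write(f">{name}\n")
            seq = rng.integers(0, 4, size=chrom_sizes[name])
            line = bases[seq].tobytes().decode()
            for i in range(0, len(line), 80):
                fh.write(line[i : i + 80] + "\n")


def _serialize_truth(truth: GroundTruth, json_path: str, bed_path: str) -> None:
    doc = {
        "chrom_sizes": truth.chrom_sizes,
        "noise": {
            "truncation_rate": truth.truncation_rate,
            "border_jitter_sd": truth.border_jitter_sd,
            "undersplit_rate": truth.undersplit_rate,
        },
        "genes": [
            {
                "name": g.name,
                "chrom": g.chrom,
                "strand": g.strand,
                "rt_tail": g.rt_tail,
                "isoforms": [
                    {"exons": iso.exons, "abundance": iso.abundance}
                    for iso in g.isoforms
                ],
            }
            for g in truth.genes
        ],
        "transients": [
            {"chrom": t.chrom, "start": t.start, "end": t.end, "strand": t.strand}
            for t in truth.transients
        ],
    }
    with open(json_path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
    with open(bed_path, "w") as fh:
        for g in truth.genes:
            for k, iso in enumerate(g.isoforms, start=1):
                fh.write(
                    bed12_line(
                        g.chrom,
                        iso.exons[0][0],
                        iso.exons[-1][1],
                        f"{g.name}.{k}",
                        int(round(iso.abundance * 1000)),
                        g.strand,
                        iso.exons,
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------


def _blocks_match(a: Sequence[Block], b: Sequence[Block], tol: int) -> bool:
    if len(a) != len(b):
        return False
    return all(
        abs(s1 - s2) <= tol and abs(e1 - e2) <= tol
        for (s1, e1), (s2, e2) in zip(a, b)
    )


def compare_to_truth(
    transcripts: Sequence[TranscriptModel],
    genes: Sequence[GeneModel],
    transients: Sequence[TransientRNA],
    truth: GroundTruth,
    tolerance: int = 0,
    min_abundance: float = 0.05,
    minor_floor: float = 0.01,
    tail_tolerance: int = 100,
    transient_jaccard: float = 0.9,
) -> Dict[str, object]:
    """Precision/recall of called models against the simulated truth.

    Transcript matching requires an equal block count with every border
    within ``tolerance`` bp.  True isoforms below ``minor_floor`` abundance
    are reported as expected-missed (the <1% filter skips them by design),
    not as false negatives.
    """
    hc = [t for t in transcripts if t.confidence == "HC"]
    iso_rows = truth.isoform_table()
    matched_iso = set()
    matched_called = set()
    for gi, (gname, chrom, strand, exons, ab) in enumerate(iso_rows):
        for t in hc:
            if t.chrom == chrom and t.strand == strand and _blocks_match(t.blocks, exons, tolerance):
                matched_iso.add(gi)
                matched_called.add(t.id)
                break
    eligible = [
        gi for gi, row in enumerate(iso_rows) if row[4] >= min_abundance
    ]
    expected_missed = [
        iso_rows[gi][0]
        for gi, row_ in zip(range(len(iso_rows)), iso_rows)
        if row_[4] < minor_floor and gi not in matched_iso
    ]
    recall = (
        sum(1 for gi in eligible if gi in matched_iso) / len(eligible)
        if eligible
        else 1.0
    )
    precision = len(matched_called) / len(hc) if hc else 1.0

    # transient recovery by best Jaccard
    recovered_tr = 0
    for unit in truth.transients:
        best = max(
            (unit.jaccard(t.interval) for t in transients
             if t.interval.strand == unit.strand and t.interval.chrom == unit.chrom),
            default=0.0,
        )
        if best >= transient_jaccard:
            recovered_tr += 1

    # RT-tail recovery: match each tailed truth gene to the overlapping called gene
    tails_checked = 0
    tails_recovered = 0
    for g in truth.genes:
        if g.rt_tail <= 0:
            continue
        span = GenomicInterval(g.chrom, g.start, g.end, g.strand)
        hit = max(
            (cg for cg in genes if cg.interval.overlaps(span)),
            key=lambda cg: cg.interval.overlap_len(span),
            default=None,
        )
        if hit is None:
            continue
        tails_checked += 1
        if abs(hit.rt_tail - g.rt_tail) <= tail_tolerance:
            tails_recovered += 1

    return {
        "isoforms_eligible": len(eligible),
        "isoform_recall": recall,
        "hc_precision": precision,
        "expected_missed": expected_missed,
        "transients_total": len(truth.transients),
        "transients_recovered": recovered_tr,
        "rt_tails_checked": tails_checked,
        "rt_tails_recovered": tails_recovered,
    }
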