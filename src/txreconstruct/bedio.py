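"""BED6 / BED12 / GFF3 serialization of pipeline outputs.

BED is written natively in the package's 0-based half-open coordinates;
GFF3 converts to 1-based inclusive on output.  All writers sort by
(chrom, start) so repeated runs are byte-identical.
"""

from __future__ import annotations

import os
from typing import Iterable, List, Optional, Sequence, Tuple

from .core import (
    FusionTranscript,
    GeneModel,
    GenomicInterval,
    ReadAlignment,
    TagCluster,
    TranscriptModel,
    TransientRNA,
    TIER_ORDER,
)

Block = Tuple[int, int]


def bed12_line(
    chrom: str,
    start: int,
    end: int,
    name: str,
    score: int,
    strand: str,
    blocks: Sequence[Block],
) -> str:
    sizes = ",".join(str(e - s) for s, e in blocks)
    starts = ",".join(str(s - start) for s, _ in blocks)
    return "\t".join(
        str(x)
        for x in (
            chrom,
            start,
            end,
            name,
            min(score, 1000),
            strand,
            start,
            end,
            "0,0,0",
            len(blocks),
            sizes + ",",
            starts + ",",
        )
    )


def write_transcripts_bed12(
    path: str, transcripts: Iterable[TranscriptModel | FusionTranscript]
) -> None:
    rows = sorted(transcripts, key=lambda t: (t.chrom, t.start, t.end, t.id))
    with open(path, "w") as fh:
        for t in rows:
            fh.write(
                bed12_line(t.chrom, t.start, t.end, t.id, t.support, t.strand, t.blocks)
                + "\n"
            )


def write_reads_bed12(path: str, reads: Iterable[ReadAlignment]) -> None:
    """Debug export of (corrected) reads; flags encoded in the name."""
    rows = sorted(reads, key=lambda r: (r.chrom, r.start, r.end, r.read_id))
    with open(path, "w") as fh:
        for r in rows:
            flags = (
                ("T" if r.tss_supported else ".")
                + ("P" if r.pas_supported else ".")
                + ("E" if r.error_flag else ".")
            )
            name = f"{r.read_id}|{flags}"
            fh.write(
                bed12_line(r.chrom, r.start, r.end, name, 0, r.strand, r.blocks) + "\n"
            )


def read_bed12(path: str) -> List[ReadAlignment]:
    """Re-import BED12 records as ReadAlignments (round-trip of the above)."""
    out: List[ReadAlignment] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{ln}: expected 12 BED fields, got {len(f)}")
            chrom, start = f[0], int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
            out.append(
                ReadAlignment(
                    read_id=f[3].split("|")[0],
                    chrom=chrom,
                    strand=f[5],
                    blocks=blocks,
                )
            )
    return out


def read_bed_intervals(path: str) -> List[GenomicInterval]:
    """BED6/BED12 reference annotation as plain stranded intervals."""
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{ln}: need at least 6 BED fields")
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), f[5]))
    return out


def read_reference_annotation(path: str) -> List[GenomicInterval]:
    """Reference genes from BED6/BED12 or GFF3 (gene-level features)."""
    if str(path).endswith((".gff", ".gff3")):
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
        out = []
        for feat in db.features_of_type("gene", order_by=("seqid", "start")):
            if feat.strand not in ("+", "-"):
                raise ValueError(f"{path}: unstranded gene feature {feat.id}")
            out.append(GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand))
        return out
    return read_bed_intervals(path)


def write_genes_bed6(path: str, genes: Iterable[GeneModel]) -> None:
    rows = sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start, g.id))
    with open(path, "w") as fh:
        for g in rows:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        g.interval.chrom,
                        g.interval.start,
                        g.interval.end,
                        g.id,
                        TIER_ORDER[g.confidence],
                        g.strand,
                    )
                )
                + "\n"
            )


def write_tag_clusters_bed6(path: str, clusters: Iterable[TagCluster]) -> None:
    """Clusters as BED6 plus a 1-bp summit companion file (<path>.summits.bed)."""
    rows = sorted(clusters, key=lambda c: (c.interval.chrom, c.interval.start, c.id))
    with open(path, "w") as fh, open(str(path) + ".summits.bed", "w") as sh:
        for c in rows:
            base = (c.interval.chrom, c.id, min(c.score, 1000), c.interval.strand)
            fh.write(
                f"{base[0]}\t{c.interval.start}\t{c.interval.end}\t{base[1]}\t{base[2]}\t{base[3]}\n"
            )
            sh.write(f"{base[0]}\t{c.summit}\t{c.summit + 1}\t{base[1]}\t{base[2]}\t{base[3]}\n")


def write_transients_bed6(path: str, transients: Iterable[TransientRNA]) -> None:
    rows = sorted(transients, key=lambda t: (t.interval.chrom, t.interval.start, t.id))
    with open(path, "w") as fh:
        for t in rows:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        t.interval.chrom,
                        t.interval.start,
                        t.interval.end,
                        f"{t.id}|{t.orientation_class}",
                        0,
                        t.interval.strand,
                    )
                )
                + "\n"
            )


def write_rt_tails_bed6(path: str, genes: Iterable[GeneModel]) -> None:
    rows = sorted(
        (g for g in genes if g.rt_tail > 0),
        key=lambda g: (g.interval.chrom, g.interval.start, g.id),
    )
    with open(path, "w") as fh:
        for g in rows:
            if g.strand == "+":
                s, e = g.interval.end, g.interval.end + g.rt_tail
            else:
                s, e = g.interval.start - g.rt_tail, g.interval.start
            fh.write(f"{g.interval.chrom}\t{s}\t{e}\t{g.id}\t{g.rt_tail}\t{g.strand}\n")


def write_gff3(
    path: str,
    genes: Sequence[GeneModel],
    transcripts: Sequence[TranscriptModel],
) -> None:
    """gene -> mRNA -> exon hierarchy, 1-based inclusive coordinates."""
    by_gene = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start, g.id)):
            iv = g.interval
            fh.write(
                f"{iv.chrom}\ttxreconstruct\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{g.strand}\t.\tID={g.id};confidence={g.confidence}\n"
            )
            for t in sorted(by_gene.get(g.id, []), key=lambda t: t.id):
                fh.write(
                    f"{t.chrom}\ttxreconstruct\tmRNA\t{t.start + 1}\t{t.end}\t"
                    f"{t.support}\t{t.strand}\t.\tID={t.id};Parent={g.id}\n"
                )
                for k, (s, e) in enumerate(t.blocks, start=1):
                    fh.write(
                        f"{t.chrom}\ttxreconstruct\texon\t{s + 1}\t{e}\t.\t"
                        f"{t.strand}\t.\tID={t.id}.exon{k};Parent={t.id}\n"
                    )
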