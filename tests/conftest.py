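import os

import pysam
import pytest

from txreconstruct import simdata
from txreconstruct.pipeline import PipelineConfig, run_pipeline


@pytest.fixture
def bam_factory(tmp_path):
    """Write a tiny sorted, indexed BAM from (name, flag, chrom, pos, cigar, mapq)."""

    def make(records, chrom_sizes={"chr1": 100_000}, name="tiny.bam"):
        path = str(tmp_path / name)
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": l} for c, l in sorted(chrom_sizes.items())],
        }
        h = pysam.AlignmentHeader.from_dict(header)
        tmp = path + ".unsorted"
        with pysam.AlignmentFile(tmp, "wb", header=header) as bam:
            for qname, flag, chrom, pos, cigar, mapq in records:
                a = pysam.AlignedSegment(h)
                a.query_name = qname
                a.flag = flag
                a.reference_id = h.get_tid(chrom)
                a.reference_start = pos
                a.cigarstring = cigar
                a.mapping_quality = mapq
                bam.write(a)
        pysam.sort("-o", path, tmp)
        os.remove(tmp)
        pysam.index(path)
        return path

    return make


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """Default-preset synthetic dataset: 10 genes, 30x, seed 1."""
    out = tmp_path_factory.mktemp("default_sim")
    truth = simdata.default_truth()
    paths = simdata.simulate_dataset(truth, depth=30, seed=1, out_dir=str(out))
    return truth, paths


@pytest.fixture(scope="session")
def default_run(default_sim, tmp_path_factory):
    truth, paths = default_sim
    out = tmp_path_factory.mktemp("default_run")
    cfg = PipelineConfig(
        long_read_bams=[paths.long_bam],
        tss_bams=paths.tss_bams,
        pas_bams=paths.pas_bams,
        nascent_bams=paths.nascent_bams,
        reference_annotation=None,
        out_dir=str(out),
    )
    result = run_pipeline(cfg)
    return truth, paths, cfg, result


def truth_internal_borders(truth):
    """Ground-truth splice-site border set (chrom, strand, side, pos)."""
    borders = set()
    for g in truth.genes:
        for iso in g.isoforms:
            for i, (s, e) in enumerate(iso.exons):
                if i > 0:
                    borders.add((g.chrom, g.strand, "L", s))
                if i < len(iso.exons) - 1:
                    borders.add((g.chrom, g.strand, "R", e))
    return borders
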