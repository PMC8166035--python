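"""Detecting an under-splitting alignment error.

Six reads share a TSS-PAS group.  Five align to the true three-exon chain;
one merges exon 1 across its intron into exon 2 (the classic long-read
aligner under-splitting artifact).  The merged read is flagged because the
constitutive exon it swallowed is absent from it, while a read with a
clean alternative donor site is tolerated.
"""

from txreconstruct.core import ReadAlignment
from txreconstruct.error_detection import flag_all

CHAIN = [(100, 200), (300, 400), (500, 600)]


def read(rid, blocks):
    r = ReadAlignment(rid, "chr1", "+", blocks)
    r.tss_supported = r.pas_supported = True
    r.tss_id, r.pas_id = "TSS_00001", "PAS_00001"
    return r


reads = [read(f"good{i}", list(CHAIN)) for i in range(5)]
reads.append(read("undersplit", [(100, 400), (500, 600)]))
reads.append(read("alt_donor", [(100, 210), (300, 400), (500, 600)]))

groups, flagged_fraction = flag_all(reads)
print(f"constitutive exons: {groups[0].constitutive_exons}")
for r in reads:
    print(f"  {r.read_id:<11} error={r.error_flag}")
print(f"flagged fraction: {flagged_fraction:.2f}")

# Only 'undersplit' is flagged: its first block spans two constitutive
# exons, so the next constitutive exon is missing from the read.  The
# alternative donor read resynchronizes on the next constitutive exon and
# is kept as a genuine alternative splice form.
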