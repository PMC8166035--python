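"""Read-through tails and transient RNAs from nascent coverage.

A gene at [4000, 5000) has nascent signal continuing 400 bp past its 3'
border (RNAPII read-through before torpedo termination), and a separate
block of nascent-only signal sits in a gene-free region (a transient RNA
invisible to poly(A)-dependent assays).
"""

import numpy as np

from txreconstruct.core import GeneModel, GenomicInterval
from txreconstruct.nascent_layer import append_rt_tails, call_nascent_intervals, call_transient_rnas, classify_orientation

depth = np.zeros(12_000, dtype=np.int32)
depth[4000:5400] = 4     # gene body + read-through tail
depth[8000:8600] = 2     # gene-free nascent unit
track = {("chr1", "+"): depth}

gene = GeneModel(
    id="HC_gene_00001",
    interval=GenomicInterval("chr1", 4000, 5000, "+"),
    confidence="HC",
    transcripts=["HC_gene_00001.1"],
)

intervals = call_nascent_intervals(track, min_depth=1, max_gap=100, min_interval_length=50)
print("nascent intervals:", [(i.interval.start, i.interval.end) for i in intervals])

pieces = append_rt_tails([gene], intervals, link_distance=100, min_tail=50)
transients = call_transient_rnas(pieces, [gene])
classify_orientation(transients, reference=None)

print(f"RT tail of {gene.id}: {gene.rt_tail} bp")
for t in transients:
    print(f"transient RNA {t.id}: [{t.interval.start}, {t.interval.end}) "
          f"orientation={t.orientation_class}")

# The 400 bp overhang past the gene's PAS becomes its RT tail; the isolated
# interval at 8000-8600 has no same-strand gene and is called transient.
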