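# Methods

This note documents the models, parameters and numerical choices behind
`txreconstruct`, what the synthetic data generator does and does not
emulate, and the design decisions taken where the procedure was genuinely
open.

## Model and assumptions

The pipeline treats the three (optionally four) assays as independent
measurements of different features of the same transcriptome:

- long spliced reads measure exon chains but have unreliable termini and
  occasional alignment artifacts;
- 5′/3′ tag libraries measure TSS/PAS positions with base-pair accuracy
  but carry no splicing information;
- nascent RNA-seq measures where RNAPII transcribes, regardless of RNA
  stability or polyadenylation.

The core assumptions are (i) the *majority* of long reads at a locus
align correctly, so majority voting denoises splice borders and defines
constitutive exons; (ii) true alternative splice sites are at least 10 bp
apart, so anything closer is alignment wobble; (iii) a read whose termini
match independently measured TSS/PAS is a complete molecule, and
everything else may be a fragment. Consequences of these assumptions are
visible in the outputs: a genuine intron-retention isoform is
indistinguishable from an under-splitting artifact unless it reaches the
constitutive majority, and rare isoforms with splice sites closer than
10 bp to a major isoform's are absorbed into it.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `max_extension` | 100 | bp | furthest a terminus is pulled to a TSS/PAS summit |
| `max_border_offset` | 10 | bp | absorption radius of border majority voting |
| `constitutive_fraction` | 0.5 | fraction | exon is constitutive iff present in strictly more than this share of its group |
| `min_isoform_fraction` | 0.01 | fraction | isoforms below this share of gene reads are skipped (strict `<`; top isoform immune) |
| `tag_max_gap` / `min_tag_count` | 25 / 3 | bp / tags | tag-cluster merging and noise floor |
| `min_sample_fraction` | 0 (off) | fraction | optional replicate-support filter for tag clusters |
| `min_mapq` | 1 | — | drops multimapping long reads |
| `nascent_min_depth` / `nascent_max_gap` / `min_interval_length` | 1 / 100 / 50 | reads / bp / bp | nascent-interval calling |
| `link_distance` / `min_tail` | 100 / 50 | bp | RT-tail attachment window and reporting threshold |
| `min_gene_overlap_bp` | 1 | bp | exonic overlap needed to merge transcripts into one gene |

The first four rows are the method's published operating points; the tag
and nascent thresholds are this implementation's defaults for steps the
method leaves unspecified, chosen to suppress singleton noise while
keeping the sharp TSS/PAS architecture of compact genomes (plant/yeast
style). All are CLI-exposed.

## Numerical and algorithmic choices

**Coordinates.** 0-based half-open everywhere; BED written natively, GFF3
converted on output. Deletions (`D`) in long-read CIGARs do not split
exons — only `N` does, because spliced aligners encode introns as `N`.
Soft-clipped bases have no reference coordinate and are ignored.

**Tag summits.** Summit = position of maximal count; ties break leftmost
on `+` and rightmost on `-` (i.e. toward the outer gene border).
Cluster ids are assigned in genomic sort order, making output deterministic.

**Extension.** Outward-only: a summit inside the read never truncates it,
and a terminus already inside a cluster is supported without moving
(truncating would discard aligner evidence). When several summits are in
range the nearest wins; a distance tie would prefer the longer read, but
ties cannot occur for one-sided candidates at distinct positions.

**Border voting.** Loci are connected components of same-strand read
*span* overlap. Left (acceptor-side) and right (donor-side) borders are
clustered independently and greedily: seed at the most frequent remaining
value (ties leftmost), absorb every value within `max_border_offset` of
the seed, rewrite members to the seed. Seeding at the mode prevents
chaining far beyond the offset; the enforced invariant is that every
member lies within the offset of its unified value. Votes are taken from
all reads in the locus, not only complete ones — jitter is unbiased
either way and incomplete reads also need clean borders for the rescue
path. Anchored termini never participate; unanchored (fragmentary)
termini do. If a rewrite would produce an empty or out-of-order block
chain the read keeps its original borders (a safeguard that cannot
trigger under the 10 bp offset with exons larger than 20 bp). The
procedure is idempotent.

**Error detection.** The walk is strand-aware (5′→3′). A deviant
subalignment overlapping two or more constitutive exons is always an
error (the swallowed exon cannot re-synchronize). A deviation with no
following constitutive exon is terminal and never flagged — the terminus
is either TSS/PAS-anchored or fragmentary, not an under-splitting
signature. Incomplete reads lack a group key; they are checked against
the constitutive chain of the single group their span overlaps, if
exactly one exists, else pass unflagged. Singleton groups make all their
exons constitutive (100% > 50%), a declared convention for degenerate
majorities. Clean exon skipping (exact borders) is never flagged.

**Gene clustering and fusions.** Genes are connected components of
same-strand exonic overlap (intron-only overlap does not merge, avoiding
nested same-strand artifacts). Fusion transcripts are found by
articulation-point removal: a transcript whose deletion splits its
component into two or more sub-components, each containing an HC
(doubly-anchored) transcript that it overlaps, is set aside as a fusion
and belongs to no gene. Gene ids are numbered per tier in coordinate
order (`HC_gene_00001`, …).

**Determinism.** No stage iterates over unordered containers when
producing output; repeated runs are byte-identical (tested).

## The synthetic data generator

`simdata` encodes the study conditions under which the pipeline is
validated. The default preset has 10 genes on two chromosomes (100 kb +
60 kb), including a convergent overlapping antisense pair, a closely
spaced tandem pair with 5% transcriptional read-through (generating
fusion reads and exercising RT-tail truncation), a two-PAS gene, an
intronless gene, and a sub-1% minor isoform that the 1% filter is
expected to miss. Long-read depth is exactly 30 per gene.

Noise model, per read:

- with probability `truncation_rate` (0.4) only a 3′ suffix survives, the
  5′ end uniform within the transcript; otherwise the 5′ end starts
  uniformly 6–40 bp downstream of the true TSS (long-read 5′ ends
  typically align a few tens of nucleotides inside the gene);
- the 3′ end sits exactly on the PAS (3′-anchored chemistry);
- each splice border is exact with probability 0.5, else offset by a
  rounded Gaussian scaled so the overall standard deviation equals
  `border_jitter_sd` (2 bp), capped at ±9 bp so that noise stays inside
  the 10 bp unification radius by construction (the `stress` preset uses
  sd 8 to exhibit the documented failure mode);
- with probability `undersplit_rate` (0.05) one intron is erased, merging
  its flanking exons.

Tag pileups use the same peaked mixture (exact with probability 0.5, else
rounded Gaussian, cap ±5 bp) around each true TSS/PAS — a plain rounded
Gaussian has a nearly flat mode and misplaces the summit by ±1 bp for
about half the sites, which misrepresents the sharp dominant position of
real 5′/3′ tag data. 60 tags per site are split across two replicate
BAMs, plus 30 uniform singleton background tags per chromosome that the
`min_tag_count` floor must remove. Nascent coverage tiles each gene body
plus its read-through tail and each transient unit with 50 bp reads at
~5× mean depth.

A separate calibration preset (five 4-exon single-isoform genes at depth
400 = 2000 reads, truncation off) isolates the error detector: every read
is complete and eligible, so the flagged fraction estimates the injected
under-splitting rate directly.

**What the generator does not emulate** — and what passing tests
therefore do not show: base-level sequencing error and basecalling,
alignment itself (reads are placed, not aligned), exitrons from
homopolymer skipping, intron-retention isoforms (indistinguishable from
under-splitting by construction of the method), expression-level
heterogeneity across genes, 3′-end heterogeneity around the PAS, and
genome-scale interval counts. Recovery rates on this fixture bound the
method's behavior under its own assumptions, not its accuracy on any real
library.

## Problem sizes

The default validation runs 300 long reads, ~1,350 tag reads and ~4,100
nascent reads through the full pipeline (well under a second); the
calibration runs 2,000 reads per rate. These sizes were chosen so that
every recovery statistic has enough support to be stable across seeds
(e.g. ≥5 expected complete reads for the rarest eligible isoform) while
the whole suite stays interactive.

## Known limitations

- Transcripts that differ only by a ragged, in-cluster 5′ end can survive
  as distinct low-support HC isoforms: a terminus already inside a TSS
  cluster is deliberately never moved, so a 3′-truncated read whose cut
  point lands inside the cluster keeps its coordinate. Recall is
  unaffected; precision on the fixture is 0.93–1.0 across seeds.
- When an exon-skipping isoform sits at exactly half the group, the
  skipped exon is not constitutive and under-splitting across it becomes
  undetectable (observed once on the default fixture at seed 1).
- Transient-RNA boundaries inherit the coverage sampling noise of their
  edges; short units near the Jaccard-0.9 recovery threshold can
  occasionally fall below it at unlucky seeds.
- The optional refinement of models against an existing reference
  annotation is limited to antisense/intergenic orientation classing;
  full annotation-guided model refinement is out of scope.
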