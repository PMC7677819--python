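# Methods

## The data plane

`colsam` re-expresses the standard germline pre-processing chain
(coordinate sorting → duplicate marking → interval-restricted base
quality update) on a columnar in-memory representation of SAM records
instead of a stream of per-record objects.

A **read batch** stores aligned reads as an Arrow record batch with one
column per SAM field: the 11 mandatory fields (QNAME, FLAG, RNAME, POS,
MAPQ, CIGAR, RNEXT, PNEXT, TLEN, SEQ, QUAL) plus a twelfth `tags` column
holding the tab-joined optional fields verbatim. The twelve-column
layout keeps every mandatory field individually addressable — each
stage touches only the handful of columns it needs — while the opaque
tags column guarantees a byte-exact round trip through SAM text. SEQ and
QUAL are stored as Phred+33 strings, not decoded integer arrays, for the
same reason; decoding happens on demand inside duplicate-ranking.

Reads are **partitioned per chromosome** at ingest (the reference
dictionary in the header defines partition identity and ordering;
`rname == '*'` reads go to a reserved unmapped partition that bypasses
sorting and duplicate marking and is re-appended at export). Every
stage then runs chromosome- or chunk-parallel, and all inter-stage data
passes through a **shared object store**: a pool of named, sealed,
immutable objects keyed `namespace/chromosome/ordinal`. Stage outputs
that change only a column or two are stored as **delta objects** — a
replacement FLAG column from duplicate marking, a (QUAL′, INDEX) pair
from the interval-filtered quality update — rather than rewritten
batches. The INDEX column maps each surviving row back to its source row
inside its chunk, so downstream consumers gather original fields by
index instead of re-evaluating intervals.

The store is backed by a directory of Arrow IPC files (one per object)
plus a JSON manifest updated under an exclusive file lock. Sealing is an
atomic rename; a `get` memory-maps the file, so retrieval does no SAM
re-parsing and no per-consumer copy of the column data, and repeated
gets leave the store's accounting unchanged. This reproduces the
create/seal/get/delete semantics of a shared-memory object store in a
form that is observable and testable across ordinary worker processes.

## Sorting and chunking

Each chromosome is sorted by POS with a stable sort; ties keep input
order, so the result is independent of worker count and completion
order. Reads with POS 0 inside a named chromosome sort first (they
precede POS ≥ 1 numerically).

Sorted partitions whose estimated size exceeds `max_bytes` (default
2 GiB) are split into chunks. The size estimate is computed, not
measured — per row, UTF-8 value bytes plus one 4-byte offset per string
column plus 4 bytes per integer column — so chunk boundaries are
deterministic and platform-independent. Cut points fall only between
rows with different POS values; a single position group larger than the
threshold becomes one oversized chunk with a warning rather than being
split. Each chunk additionally carries read-only **padding rows**: copies
of all neighbour rows whose POS lies within `pad_bp` of the chunk's cut
positions. Padding rows take part in window-local computations but never
receive outputs — their owning chunk decides them.

## Duplicate marking

The grouping coordinate of a read is its unclipped 5′ end on the
sequencing strand: POS minus leading soft/hard clips for a forward read,
or the rightmost reference position (POS + reference-consumed CIGAR
length − 1) plus trailing clips for a reverse read. Paired reads are
grouped by the canonically ordered combination of both mates' ends and
strands, so both mates — possibly processed in different partitions —
compute the same key without communicating. The mate's unclipped end is
derived from the MC (mate CIGAR) tag when present; otherwise PNEXT is
used without clip correction and a warning counter is kept per chunk.

Within a group the highest-scoring member survives; all others get FLAG
bit 0x400. Two scoring strategies are provided: `sum_of_base_qualities`
(sum of Phred values ≥ 15 over the read, summed over both mates of a
pair when both are visible; the default) and `total_mapped_length`
(query bases consumed by M/=/X) for data without usable base qualities.
Ties break deterministically by (score descending, QNAME ascending).
An unpaired read whose end coincides with a paired read's end is marked
as a duplicate of the pair regardless of score (a fragment never
outranks a pair). Secondary (0x100), supplementary (0x800) and unmapped
reads are never candidates and never marked. Optical-duplicate distance
handling and library-aware (LB) grouping are out of scope; records are
marked, never removed.

**Chunk invariance.** Duplicate decisions are local to a position
window, so per-chunk marking reproduces the whole-chromosome result
exactly provided every member of a boundary-straddling group is visible
from every chunk that owns one of its members. For single-end data a
padding of `max read span + max clip` suffices; for paired data the
group decision involves both mates, so the requirement is `pad_bp ≥
maximum template span + max clip`. The default `pad_bp = 1000` covers
typical short-read libraries (insert ≲ 800 bp); with shorter padding the
per-chunk results remain deterministic but may differ from the
unchunked run for groups straddling a cut. When the two mates of a pair
map to different chromosomes, each side ranks its group by the locally
visible scores; two sides of a cross-chromosome duplicate pair could in
principle disagree when per-mate score orderings differ.

## Interval filtering and quality update

Interval membership uses reference-span overlap, matching `-L`-style
semantics: a read survives when [POS, POS + reference-consumed(CIGAR) −
1] (1-based inclusive) overlaps any interval of its chromosome. BED
input is 0-based half-open; BED start+1 is the first 1-based base.
Intervals are merged (including adjacent ones) and sorted at load;
membership is a binary search over the merged starts. Rows with CIGAR
`'*'` or POS 0 never survive.

The quality update itself is a pluggable per-base Phred→Phred mapping
(`identity` and `shift:<delta>` ship with the CLI); the covariate-model
machinery of full base-quality recalibration is deliberately out of
scope — this package provides the data plane (field projections,
filtering, the delta/INDEX mechanism) that such a model plugs into. A
transform output outside Phred 0..93 raises, but only when the offending
source quality actually occurs in the filtered reads.

Each stage sees only its projection of the columns:

| stage            | fields |
|------------------|--------|
| markdup          | QNAME, FLAG, RNAME, POS, CIGAR, RNEXT |
| bqsr / applybqsr | RNAME, POS, MAPQ, CIGAR, SEQ, QUAL + FLAG (from the FLAG delta) |
| haplotypecaller  | RNAME, POS, MAPQ, CIGAR, SEQ + FLAG + QUAL′, INDEX (from the deltas) |

## Synthetic data generator

The generator emulates aligner output with known structure: paired-end
(FR, proper-pair flags, MC tags, template span bounded by `max_insert`,
default 300 bp) and single-end reads, soft clipping (probability 0.3 up
to 10 bp by default), ~1% cross-chromosome mates, ~2% unmapped reads,
per-base qualities uniform in Phred 20–40, uniformly shuffled record
order, over a 25-reference human-style dictionary (small reference
lengths — 150 kb autosomes — keep desk-scale runs fast; partition
structure, not genome size, is what the stages depend on).

Planted duplicate groups share unclipped 5′ ends by construction while
members differ in soft clip, so the clip-corrected geometry is genuinely
exercised. Each member receives a distinct constant per-read quality
with one boosted winner (Phred 41 vs 17–20), making the expected
survivor unambiguous: truth tables are independent of tie-breaking. All
other reads receive unclipped ends unique within their (chromosome,
strand), so no accidental groups arise — which is what makes exact
truth-table comparison a valid test. Consequences of these
simplifications: the generator does not model sequencing error, indel
CIGARs, realistic quality profiles, coverage waves or optical-duplicate
pixel geometry, so passing tests demonstrate the correctness of the data
plane's bookkeeping (grouping geometry, ordering, delta application,
conservation), not calling accuracy on real libraries.

## Numerical and design choices

- **Stability everywhere**: sorting is stable, worker results are
  collated by (header chromosome order, ordinal), and all tie-breaks are
  lexicographic — identical (input, config, seed) gives byte-identical
  output for any worker count.
- **Conservation**: every input row is owned by exactly one chunk;
  export equals input minus interval-filtered rows, checked in the run
  report.
- **Degenerate inputs**: empty batches, header-only SAM, empty interval
  sets, single-read groups and all-unmapped inputs are all defined and
  tested; oversized single-position groups are kept whole with a
  warning.
- **Problem sizes** in the test suite and the reproduction script are
  desk-scale by design (≈50 k reads for round-trip/sort checks, ≈5 k
  reads with 220 planted groups for duplicate truth, 1 KB chunk
  thresholds to force deep multi-chunk paths); the properties they check
  are size-independent.

## Known limitations

- SAM text only (no BAM/CRAM, no gzip); no query-name sorting.
- Cross-chromosome duplicate pairs: see the chunk-invariance note above.
- Without MC tags the mate end falls back to PNEXT (no clip
  correction), which can merge or split groups relative to a
  clip-corrected run; the per-run warning counter reports how often the
  fallback fired.
- The store bounds its size only by an optional capacity (hard error,
  no eviction), matching the assumption that working data fits in
  memory.
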