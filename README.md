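# colsam

A columnar in-memory data plane for SAM alignment pre-processing.

Standard germline variant-calling workflows spend much of their time
shuttling alignment records between tools as (compressed) files: each
stage re-parses, re-serializes and re-writes the whole record stream.
`colsam` instead keeps aligned reads **column-wise** — one Arrow array
per SAM field, one record batch per chromosome — in a pool of named,
sealed, immutable shared objects, and re-expresses the pre-processing
stages directly on that representation:

- **ingest** — parse SAM text once into per-chromosome columnar
  partitions (the `tags` column keeps optional fields verbatim, so
  export is byte-exact);
- **sort** — stable coordinate sort per chromosome, chromosome-parallel;
  partitions above a size threshold are split into chunks with padded
  boundaries;
- **markdup** — duplicate marking by unclipped 5′ end and orientation
  (pairs grouped by both ends, Picard-style `sum_of_base_qualities`
  ranking), emitted as a *FLAG delta* column per chunk rather than a
  rewritten batch;
- **filter** — BED-interval filtering with reference-span overlap
  semantics plus a pluggable per-base quality transform, emitted as a
  (QUAL′, INDEX) delta whose INDEX column maps each surviving row back
  to its source row;
- **export** — merged (or per-chromosome) SAM with all deltas applied,
  in header order, coordinate-sorted, unmapped reads last.

Every stage exchanges data only through the object store, runs
chunk-parallel, and produces results byte-identical to a serial,
unchunked run. A bundled synthetic-read generator produces realistic
inputs (pairs, soft clips, cross-chromosome mates, unmapped reads) with
a machine-readable duplicate truth table, so the whole plane is testable
without external datasets.

The intended audience is developers of genomics pipelines and tooling
who need a correct, deterministic, inspectable pre-processing core —
not a drop-in replacement for a full recalibration/variant-calling
stack (the quality-model and calling algorithms themselves are
pluggable externals; see `docs/methods.md`).

## The model in brief

For a read with leftmost position `p` and CIGAR `c`, the duplicate
grouping coordinate is the unclipped 5′ end on the sequencing strand:

```
forward:  u = p − (leading soft/hard clips of c)
reverse:  u = p + (reference-consumed length of c) − 1 + (trailing clips)
```

Reads (or read pairs, keyed by the canonically ordered pair of both
mates' `(chromosome, u, strand)`) that share a key form a duplicate
group; the member with the highest score `S = Σ{q : q ≥ 15}` over its
base qualities `q` (summed over both mates when visible) survives, and
every other member gets FLAG bit 0x400. Interval filtering keeps a read
iff `[p, p + reflen(c) − 1]` overlaps a BED interval (0-based,
half-open, converted to 1-based inclusive).

## Worked example

```bash
colsam simulate --out sample.sam --truth truth.tsv \
    --n-fragments 1000 --duplicate-groups 60 --seed 7
# wrote 2048 reads to sample.sam

colsam pipeline --in sample.sam --out final.sam --workers 4 --report report.json
```

The run report (`report.json`) summarizes the stages:

```json
{
  "input_reads": 2048,
  "sorted_reads": 2048,
  "duplicates_total": 229,
  "filtered_out": 0,
  "exported": 2048,
  "conservation_ok": true
}
```

2048 simulated reads were ingested into 26 partitions (chr1–chr22, X,
Y, M and the unmapped `'*'` partition), sorted, and 229 reads were
flagged as duplicates — exactly the reads the simulator's truth table
(`truth.tsv`) planted as redundant copies, e.g. both mates of the
losing pair `grp0059_m1` in `final.sam` now carry bit 0x400
(FLAG 1123/1171 instead of 99/147):

```
grp0059_m1  1123  chr1  95234  60  100M  =  95392   258  ...
grp0059_m1  1171  chr1  95392  60  100M  =  95234  -258  ...
```

`conservation_ok` asserts `input = exported + filtered-out`; with a BED
file (`--bed targets.bed`) the export keeps only interval-overlapping
reads and the filtered count becomes non-zero.

The same stages are available individually (`colsam ingest`, `sort`,
`markdup`, `filter`, `export`, with `colsam store ls` to inspect the
object pool), and as a library:

```python
from colsam import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(input_sam="sample.sam",
                                     out="final.sam", workers=4))
```

## Layout

```
src/colsam/
  model.py      # ReadBatch / Chunk / Partition, validation, CIGAR math
  samio.py      # byte-faithful SAM text I/O, BED parsing and merging
  store.py      # shared pool of sealed immutable Arrow IPC objects
  partition.py  # per-chromosome routing, chunk splitting with padding
  sort.py       # stable coordinate sort, chromosome-parallel driver
  markdup.py    # duplicate marking -> FLAG delta objects
  views.py      # stage projections, interval filter, (QUAL', INDEX) deltas, export
  pipeline.py   # orchestration, run report, YAML config
  simulate.py   # synthetic reads with duplicate-truth tables
  cli.py        # `colsam` command-line interface
```

See `docs/methods.md` for the model, its assumptions, parameter
defaults and known limitations.
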