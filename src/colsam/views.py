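"""Stage field projections, interval filtering and delta resolution.

Each downstream consumer touches only a subset of the twelve columns;
:func:`stage_view` exposes exactly that subset, overlaying the FLAG
delta produced by duplicate marking and — for the variant-calling view —
the (QUAL′, INDEX) delta produced by the interval-filtered quality
update.  The INDEX column maps each surviving row back to its source row
within the chunk's owned rows, so downstream stages gather original
fields by index instead of re-evaluating intervals.

Interval membership uses reference-span overlap: a read survives when
its aligned span [POS, POS + reference-consumed(CIGAR) − 1] (1-based,
inclusive) overlaps any interval of its chromosome.  BED coordinates are
0-based half-open, so BED start+1 is the first 1-based base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pyarrow as pa

from .model import (
    Chunk,
    ColsamError,
    ReadBatch,
    SamHeader,
    cigar_reference_span,
    concat_batches,
    slice_rows,
)
from .samio import IntervalSet, sam_lines
from .store import ObjectKey, ObjectStore, StoreError

__all__ = ["STAGE_FIELDS", "StageView", "stage_view", "filter_by_intervals",
           "apply_qual_transform", "QualIndexDelta", "resolve_reads",
           "export_final"]

#: Exact column set each stage may touch, in field order.
STAGE_FIELDS = {
    "markdup": ("QNAME", "FLAG", "RNAME", "POS", "CIGAR", "RNEXT"),
    "bqsr": ("RNAME", "POS", "MAPQ", "CIGAR", "SEQ", "QUAL", "FLAG"),
    "applybqsr": ("RNAME", "POS", "MAPQ", "CIGAR", "SEQ", "QUAL", "FLAG"),
    "haplotypecaller": ("RNAME", "POS", "MAPQ", "CIGAR", "SEQ", "FLAG",
                        "QUAL", "INDEX"),
}

_PHRED_MAX = 93


@dataclass
class StageView:
    """A stage's projected columns — nothing else is reachable."""

    stage: str
    columns: dict[str, object]

    def names(self) -> tuple[str, ...]:
        return tuple(self.columns)


@dataclass
class QualIndexDelta:
    """(QUAL′, INDEX) column pair for one chunk's surviving rows.

    ``index`` holds strictly increasing 0-based indices into the chunk's
    owned rows; ``qual`` holds the replacement Phred+33 string for each
    surviving row, same base count as the source.
    """

    qual: list[str]
    index: np.ndarray
    key: ObjectKey | None = None

    payload_kind = "qualindex"

    def __len__(self) -> int:
        return len(self.index)

    def check(self, chunk: Chunk | None = None) -> None:
        if len(self.qual) != len(self.index):
            raise ColsamError(
                f"qual/index length mismatch: {len(self.qual)} vs "
                f"{len(self.index)}")
        if len(self.index) > 1 and np.any(np.diff(self.index) <= 0):
            raise ColsamError("INDEX column must be strictly increasing")
        if chunk is not None:
            if len(self.index) and int(self.index.max()) >= chunk.num_rows:
                raise ColsamError(
                    f"INDEX {int(self.index.max())} out of range for chunk "
                    f"of {chunk.num_rows} owned rows")
            src = chunk.batch.strings("qual")
            for k, i in enumerate(self.index):
                s = src[int(i)]
                if s != "*" and self.qual[k] != "*" and len(s) != len(self.qual[k]):
                    raise ColsamError(
                        f"replacement qual length {len(self.qual[k])} != "
                        f"source {len(s)} at index {int(i)}")

    def to_record_batch(self) -> pa.RecordBatch:
        return pa.record_batch(
            [pa.array(self.qual, type=pa.string()),
             pa.array(self.index, type=pa.int64())],
            names=["qual", "index"],
        ).replace_schema_metadata({b"colsam_kind": b"qualindex"})

    @classmethod
    def from_record_batch(cls, rb: pa.RecordBatch) -> "QualIndexDelta":
        return cls(
            qual=rb.column(0).to_pylist(),
            index=rb.column(1).to_numpy(zero_copy_only=False).astype(np.int64),
        )


def stage_view(chunk: Chunk, stage: str,
               flag_delta=None, qual_index=None) -> StageView:
    """Project a chunk to exactly the column set one stage may access."""
    if stage not in STAGE_FIELDS:
        raise ColsamError(f"unknown stage {stage!r}; "
                          f"expected one of {sorted(STAGE_FIELDS)}")
    batch = chunk.batch
    if stage in ("bqsr", "applybqsr", "haplotypecaller") and flag_delta is None:
        raise ColsamError(
            f"stage {stage!r} requires the 'flagdelta' namespace output")
    if stage == "haplotypecaller" and qual_index is None:
        raise ColsamError(
            "stage 'haplotypecaller' requires the 'qualindex' namespace output")
    cols: dict[str, object] = {}
    for name in STAGE_FIELDS[stage]:
        if name == "FLAG" and flag_delta is not None:
            cols[name] = np.asarray(flag_delta.flags, dtype=np.int64)
        elif name == "QUAL" and stage == "haplotypecaller":
            cols[name] = list(qual_index.qual)
        elif name == "INDEX":
            cols[name] = np.asarray(qual_index.index, dtype=np.int64)
        else:
            field = name.lower()
            if field in ("flag", "pos", "mapq", "pnext", "tlen"):
                cols[name] = batch.ints(field)
            else:
                cols[name] = batch.strings(field)
    return StageView(stage, cols)


def filter_by_intervals(chunk: Chunk, intervals: IntervalSet) -> np.ndarray:
    """0-based indices (strictly increasing) of owned rows whose aligned
    reference span overlaps an interval of their chromosome.

    Unaligned rows (CIGAR ``'*'`` or POS 0) never survive.
    """
    batch = chunk.batch
    n = batch.num_rows
    if n == 0:
        return np.empty(0, dtype=np.int64)
    pos = batch.ints("pos")
    cigars = batch.strings("cigar")
    rnames = batch.strings("rname")
    out: list[int] = []
    cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for i in range(n):
        if cigars[i] == "*" or pos[i] < 1:
            continue
        starts, ends = cache.get(rnames[i]) or cache.setdefault(
            rnames[i], intervals.for_chrom(rnames[i]))
        if not len(starts):
            continue
        # read span, converted to BED's 0-based half-open coordinates
        r0 = int(pos[i]) - 1
        r1 = r0 + cigar_reference_span(cigars[i])
        # candidate: last interval starting before the read ends
        j = int(np.searchsorted(starts, r1, side="left")) - 1
        if j >= 0 and ends[j] > r0:
            out.append(i)
    return np.asarray(out, dtype=np.int64)


def _phred_table(transform) -> tuple[bytes, bytes]:
    """(translation table, invalid source chars) over Phred+33 characters
    for a transform given either as a mapping or a callable on Phred
    values 0..93.  A transform output outside 0..93 is an error only if
    the offending source quality actually occurs in the data."""
    table = bytearray(range(256))
    invalid = bytearray()
    for q in range(_PHRED_MAX + 1):
        q2 = transform(q) if callable(transform) else transform.get(q, q)
        if 0 <= q2 <= _PHRED_MAX:
            table[q + 33] = q2 + 33
        else:
            invalid.append(q + 33)
    return bytes(table), bytes(invalid)


def apply_qual_transform(chunk: Chunk, index: np.ndarray,
                         transform) -> QualIndexDelta:
    """Map every base quality of the surviving rows through ``transform``
    (a dict or callable on Phred values); lengths are preserved and the
    index is stored alongside as the back-mapping column."""
    index = np.asarray(index, dtype=np.int64)
    if len(index) and (index.min() < 0 or index.max() >= chunk.num_rows):
        raise ColsamError("index out of range for chunk")
    table, invalid = _phred_table(transform)
    src = chunk.batch.strings("qual")
    qual: list[str] = []
    for i in index:
        s = src[int(i)]
        if s == "*":
            qual.append("*")
            continue
        enc = s.encode("ascii")
        if invalid and len(enc.translate(None, invalid)) != len(enc):
            bad = next(c for c in enc if c in invalid)
            raise ColsamError(
                f"quality transform maps Phred {bad - 33} outside 0..93 "
                f"(row index {int(i)})")
        qual.append(enc.translate(table).decode("ascii"))
    return QualIndexDelta(qual=qual, index=index)


def resolve_reads(chunk: Chunk, flag_delta=None,
                  qual_index=None) -> ReadBatch:
    """Materialize a chunk's final reads: gather source rows by INDEX and
    substitute the delta FLAG and QUAL columns.

    With no deltas this is the identity on the chunk's owned rows.
    """
    batch = chunk.batch
    if flag_delta is not None and len(flag_delta.flags) != batch.num_rows:
        raise ColsamError(
            f"flag delta length {len(flag_delta.flags)} != owned rows "
            f"{batch.num_rows}")
    if qual_index is not None:
        qual_index.check(chunk)
        index = np.asarray(qual_index.index, dtype=np.int64)
    else:
        index = np.arange(batch.num_rows, dtype=np.int64)
    flags = (np.asarray(flag_delta.flags, dtype=np.int64)
             if flag_delta is not None else batch.ints("flag"))
    out = slice_rows(batch, index)
    arrays = []
    for j, name in enumerate(out.data.schema.names):
        if name == "flag":
            arrays.append(pa.array(flags[index], type=pa.int32()))
        elif name == "qual" and qual_index is not None:
            arrays.append(pa.array(qual_index.qual, type=pa.string()))
        else:
            arrays.append(out.data.column(j))
    return ReadBatch(pa.record_batch(arrays, names=list(out.data.schema.names)))


def export_final(store: ObjectStore, header: SamHeader, out,
                 per_chrom: bool = False,
                 sorted_namespace: str = "sorted",
                 flag_namespace: str = "flagdelta",
                 qual_namespace: str = "qualindex") -> int:
    """Export the pipeline's final reads as SAM text.

    Chromosomes are written in header reference order, coordinate order
    within each, unmapped reads last; FLAG and QUAL reflect whatever
    deltas exist in the store.  With ``per_chrom`` set, ``out`` is a
    directory receiving one SAM file per chromosome (plus
    ``unmapped.sam``); otherwise one merged file.
    """
    keys = store.list_keys(sorted_namespace)
    if not keys:
        raise StoreError(f"no objects in namespace {sorted_namespace!r}")
    qual_keys = {k for k in store.list_keys(qual_namespace)}
    flag_keys = {k for k in store.list_keys(flag_namespace)}
    filtering = bool(qual_keys)

    by_chrom: dict[str, list[ObjectKey]] = {}
    for k in keys:
        by_chrom.setdefault(k.chrom, []).append(k)

    def chrom_batch(chrom: str) -> ReadBatch:
        parts = []
        for k in sorted(by_chrom[chrom], key=lambda k: k.ordinal):
            chunk = store.get(k)
            fd_key = ObjectKey(flag_namespace, k.chrom, k.ordinal)
            fd = store.get(fd_key) if fd_key in flag_keys else None
            qd = None
            if filtering:
                qi_key = ObjectKey(qual_namespace, k.chrom, k.ordinal)
                if qi_key not in qual_keys:
                    raise StoreError(
                        f"interval filtering active but {qi_key.name!r} "
                        "is missing")
                qd = store.get(qi_key)
            parts.append(resolve_reads(chunk, fd, qd))
        return concat_batches(parts)

    chrom_order = [c for c in header.references if c in by_chrom]
    if "*" in by_chrom:
        chrom_order.append("*")

    total = 0
    if per_chrom:
        from pathlib import Path
        outdir = Path(out)
        outdir.mkdir(parents=True, exist_ok=True)
        for chrom in chrom_order:
            batch = chrom_batch(chrom)
            name = "unmapped.sam" if chrom == "*" else f"{chrom}.sam"
            from .samio import write_sam
            total += write_sam(header, batch, outdir / name)
        return total

    close = False
    if isinstance(out, (str, bytes)) or hasattr(out, "__fspath__"):
        sink = open(out, "w", encoding="utf-8", newline="")
        close = True
    else:
        sink = out
    try:
        sink.write(header.serialize())
        for chrom in chrom_order:
            for line in sam_lines(chrom_batch(chrom)):
                sink.write(line)
                sink.write("\n")
                total += 1
    finally:
        if close:
            sink.close()
    return total
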