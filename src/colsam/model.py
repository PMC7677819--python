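"""Columnar in-memory model of SAM alignment records.

A :class:`ReadBatch` holds aligned reads column-wise as an Arrow record
batch with one column per SAM field: the 11 mandatory fields plus a
``tags`` column that carries the tab-joined optional fields verbatim,
for twelve columns in total.  Keeping the optional fields as one opaque
string column preserves byte-exact round-trips through SAM text while
the mandatory fields stay individually addressable, which is what the
downstream stages (sorting, duplicate marking, interval filtering) need.

Reads are grouped per chromosome into a :class:`Partition`, an ordered
list of bounded-size :class:`Chunk` objects.  A chunk owns a contiguous
run of coordinate-sorted rows and may additionally carry read-only
*padding* rows copied from its neighbours, so that window-local
computations (duplicate grouping in particular) see complete candidate
groups that straddle a chunk boundary.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

import numpy as np
import pyarrow as pa

__all__ = [
    "SAM_FIELDS",
    "SAM_SCHEMA",
    "ColsamError",
    "SamParseError",
    "StoreError",
    "SchemaMismatchError",
    "SortOrder",
    "SamHeader",
    "ReadBatch",
    "Chunk",
    "Partition",
    "Violation",
    "validate_batch",
    "concat_batches",
    "slice_rows",
    "parse_cigar",
    "cigar_query_length",
    "cigar_reference_span",
    "leading_clip",
    "trailing_clip",
    "approx_row_bytes",
    "approx_batch_bytes",
]

#: The twelve columns of the in-memory representation, in SAM field order.
SAM_FIELDS = (
    "qname", "flag", "rname", "pos", "mapq", "cigar",
    "rnext", "pnext", "tlen", "seq", "qual", "tags",
)

_INT_FIELDS = ("flag", "pos", "mapq", "pnext", "tlen")

SAM_SCHEMA = pa.schema(
    [
        pa.field("qname", pa.string()),
        pa.field("flag", pa.int32()),
        pa.field("rname", pa.string()),
        pa.field("pos", pa.int32()),
        pa.field("mapq", pa.int32()),
        pa.field("cigar", pa.string()),
        pa.field("rnext", pa.string()),
        pa.field("pnext", pa.int32()),
        pa.field("tlen", pa.int32()),
        pa.field("seq", pa.string()),
        pa.field("qual", pa.string()),
        pa.field("tags", pa.string()),
    ]
)

# SAM FLAG bits used throughout the package.
FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_QCFAIL = 0x200
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800


class ColsamError(Exception):
    """Base class for all errors raised by this package."""


class SamParseError(ColsamError):
    """Malformed SAM or BED text; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class StoreError(ColsamError):
    """Object-store contract violation (missing/duplicate/unsealed key)."""


class SchemaMismatchError(ColsamError):
    """Batches with incompatible schemas were combined."""


# ---------------------------------------------------------------------------
# CIGAR helpers
# ---------------------------------------------------------------------------

_CIGAR_OP_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_CIGAR_FULL_RE = re.compile(r"^(?:\d+[MIDNSHP=X])+$")

#: operators that consume query bases / reference bases
_QUERY_OPS = frozenset("MIS=X")
_REF_OPS = frozenset("MDN=X")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Split a CIGAR string into ``(length, op)`` tuples.

    Raises :class:`ColsamError` for anything that is not ``'*'`` or a
    well-formed CIGAR; ``'*'`` yields an empty list.
    """
    if cigar == "*":
        return []
    if not _CIGAR_FULL_RE.match(cigar):
        raise ColsamError(f"malformed CIGAR string: {cigar!r}")
    return [(int(n), op) for n, op in _CIGAR_OP_RE.findall(cigar)]


def cigar_query_length(cigar: str) -> int:
    """Number of query (read) bases consumed by the alignment."""
    return sum(n for n, op in parse_cigar(cigar) if op in _QUERY_OPS)


def cigar_reference_span(cigar: str) -> int:
    """Number of reference bases consumed by the alignment."""
    return sum(n for n, op in parse_cigar(cigar) if op in _REF_OPS)


def leading_clip(cigar: str) -> int:
    """Total soft+hard clip length at the start of the CIGAR."""
    total = 0
    for n, op in parse_cigar(cigar):
        if op in "SH":
            total += n
        else:
            break
    return total


def trailing_clip(cigar: str) -> int:
    """Total soft+hard clip length at the end of the CIGAR."""
    total = 0
    for n, op in reversed(parse_cigar(cigar)):
        if op in "SH":
            total += n
        else:
            break
    return total


# ---------------------------------------------------------------------------
# Header
# ---------------------------------------------------------------------------


class SortOrder(str, enum.Enum):
    unknown = "unknown"
    unsorted = "unsorted"
    queryname = "queryname"
    coordinate = "coordinate"


@dataclass
class SamHeader:
    """A SAM header: verbatim lines plus the parsed reference dictionary.

    ``raw_lines`` round-trips byte-identically; ``references`` maps each
    reference name (from ``@SQ`` ``SN``/``LN``) to its length in bases,
    in header order, which also defines chromosome ordering everywhere
    downstream.
    """

    raw_lines: list[str] = field(default_factory=list)
    references: dict[str, int] = field(default_factory=dict)
    sort_order: SortOrder = SortOrder.unknown

    @classmethod
    def parse(cls, lines: list[str]) -> "SamHeader":
        references: dict[str, int] = {}
        sort_order = SortOrder.unknown
        for i, line in enumerate(lines, start=1):
            if not line.startswith("@"):
                raise SamParseError("header line must start with '@'", i)
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "@SQ":
                sn, ln = None, None
                for f in fields[1:]:
                    if f.startswith("SN:"):
                        sn = f[3:]
                    elif f.startswith("LN:"):
                        try:
                            ln = int(f[3:])
                        except ValueError:
                            raise SamParseError(f"non-integer @SQ LN: {f[3:]!r}", i)
                if sn is None or ln is None:
                    raise SamParseError("@SQ line missing SN or LN", i)
                if sn in references:
                    raise SamParseError(f"duplicate @SQ reference name {sn!r}", i)
                if ln <= 0:
                    raise SamParseError(f"non-positive @SQ LN for {sn!r}", i)
                references[sn] = ln
            elif fields[0] == "@HD":
                for f in fields[1:]:
                    if f.startswith("SO:"):
                        try:
                            sort_order = SortOrder(f[3:])
                        except ValueError:
                            sort_order = SortOrder.unknown
        return cls(list(lines), references, sort_order)

    def serialize(self) -> str:
        if not self.raw_lines:
            return ""
        return "\n".join(line.rstrip("\n") for line in self.raw_lines) + "\n"

    def chrom_rank(self) -> dict[str, int]:
        """Reference name -> position in header order; '*' sorts last."""
        rank = {name: i for i, name in enumerate(self.references)}
        rank["*"] = len(rank)
        return rank


# ---------------------------------------------------------------------------
# ReadBatch
# ---------------------------------------------------------------------------


def _coerce_batch(data: pa.RecordBatch) -> pa.RecordBatch:
    if data.schema.names != list(SAM_FIELDS):
        raise SchemaMismatchError(
            f"expected columns {list(SAM_FIELDS)}, got {data.schema.names}"
        )
    if not data.schema.equals(SAM_SCHEMA):
        data = pa.record_batch(
            [data.column(i).cast(SAM_SCHEMA.field(i).type) for i in range(len(SAM_FIELDS))],
            schema=SAM_SCHEMA,
        )
    return data


@dataclass
class ReadBatch:
    """Columnar table of aligned reads, one Arrow array per SAM field."""

    data: pa.RecordBatch

    def __post_init__(self):
        self.data = _coerce_batch(self.data)

    # -- constructors ------------------------------------------------------
    @classmethod
    def empty(cls) -> "ReadBatch":
        return cls(pa.record_batch(
            [pa.array([], type=f.type) for f in SAM_SCHEMA], schema=SAM_SCHEMA))

    @classmethod
    def from_pydict(cls, columns: dict[str, list]) -> "ReadBatch":
        arrays = []
        n = None
        for name in SAM_FIELDS:
            values = columns.get(name)
            if values is None:
                raise SchemaMismatchError(f"missing column {name!r}")
            if n is None:
                n = len(values)
            elif len(values) != n:
                raise SchemaMismatchError(
                    f"column {name!r} has {len(values)} rows, expected {n}")
            arrays.append(pa.array(values, type=SAM_SCHEMA.field(name).type))
        return cls(pa.record_batch(arrays, schema=SAM_SCHEMA))

    # -- accessors ---------------------------------------------------------
    @property
    def num_rows(self) -> int:
        return self.data.num_rows

    def __len__(self) -> int:
        return self.data.num_rows

    def column(self, name: str) -> pa.Array:
        return self.data.column(SAM_FIELDS.index(name))

    def strings(self, name: str) -> list[str]:
        """Column as a python list of str (string columns only)."""
        return self.column(name).to_pylist()

    def ints(self, name: str) -> np.ndarray:
        """Column as a numpy int64 array (integer columns only)."""
        return self.column(name).to_numpy(zero_copy_only=False).astype(np.int64)

    def row(self, i: int) -> dict:
        return {name: self.data.column(j)[i].as_py() for j, name in enumerate(SAM_FIELDS)}

    def equals(self, other: "ReadBatch") -> bool:
        return self.data.equals(other.data)

    def __eq__(self, other) -> bool:  # value equality, convenient in tests
        return isinstance(other, ReadBatch) and self.equals(other)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    """One broken :class:`ReadBatch` invariant, located by row and column."""

    row: int
    column: str
    rule: str

    def __str__(self) -> str:
        return f"{self.rule} at row {self.row} (column {self.column})"


def validate_batch(batch: ReadBatch) -> list[Violation]:
    """Check every ReadBatch invariant; violations are returned, not raised.

    Rules checked per row: non-negative ``pos``/``pnext``, ``mapq`` and
    ``flag`` ranges, CIGAR well-formedness, SEQ/QUAL length agreement and
    CIGAR/SEQ query-length agreement (each only when the fields are
    present, i.e. not ``'*'``).
    """
    out: list[Violation] = []
    n = batch.num_rows
    if n == 0:
        return out
    flag = batch.ints("flag")
    pos = batch.ints("pos")
    mapq = batch.ints("mapq")
    pnext = batch.ints("pnext")
    cigar = batch.strings("cigar")
    seq = batch.strings("seq")
    qual = batch.strings("qual")
    for i in range(n):
        if not (0 <= flag[i] <= 0xFFFF):
            out.append(Violation(i, "flag", f"flag {flag[i]} outside 0..65535"))
        if pos[i] < 0:
            out.append(Violation(i, "pos", f"negative pos {pos[i]}"))
        if pnext[i] < 0:
            out.append(Violation(i, "pnext", f"negative pnext {pnext[i]}"))
        if not (0 <= mapq[i] <= 255):
            out.append(Violation(i, "mapq", f"mapq {mapq[i]} outside 0..255"))
        qlen = None
        if cigar[i] != "*":
            try:
                qlen = cigar_query_length(cigar[i])
            except ColsamError:
                out.append(Violation(i, "cigar", f"malformed CIGAR {cigar[i]!r}"))
        if seq[i] != "*" and qual[i] != "*" and len(seq[i]) != len(qual[i]):
            out.append(Violation(i, "qual", "seq/qual length mismatch"))
        if qlen is not None and seq[i] != "*" and qlen != len(seq[i]):
            out.append(Violation(
                i, "cigar",
                f"CIGAR query length {qlen} != seq length {len(seq[i])}"))
    return out


# ---------------------------------------------------------------------------
# Concatenation / slicing
# ---------------------------------------------------------------------------


def concat_batches(batches: list[ReadBatch]) -> ReadBatch:
    """Concatenate batches row-wise, preserving input order bit-exactly."""
    batches = [b for b in batches]
    if not batches:
        return ReadBatch.empty()
    if len(batches) == 1:
        return ReadBatch(batches[0].data)
    for b in batches:
        if b.data.schema.names != list(SAM_FIELDS):
            bad = set(b.data.schema.names) ^ set(SAM_FIELDS)
            raise SchemaMismatchError(f"schema mismatch on column(s) {sorted(bad)}")
    table = pa.Table.from_batches([b.data for b in batches]).combine_chunks()
    if table.num_rows == 0:
        return ReadBatch.empty()
    parts = table.to_batches()
    assert len(parts) == 1
    return ReadBatch(parts[0])


def slice_rows(batch: ReadBatch, row_indices) -> ReadBatch:
    """Gather rows by 0-based index (the INDEX-column primitive).

    Output row ``k`` equals input row ``row_indices[k]`` for every column.
    """
    idx = np.asarray(row_indices, dtype=np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= batch.num_rows):
        bad = idx[(idx < 0) | (idx >= batch.num_rows)][0]
        raise ColsamError(
            f"row index {bad} out of range for batch of {batch.num_rows} rows")
    return ReadBatch(batch.data.take(pa.array(idx, type=pa.int64())))


# ---------------------------------------------------------------------------
# Size accounting
# ---------------------------------------------------------------------------

_INT_WIDTH = 4          # all integer columns are int32
_OFFSET_WIDTH = 4       # string offset entries are int32


def approx_row_bytes(batch: ReadBatch) -> np.ndarray:
    """Estimated in-memory bytes of each row: value bytes plus offsets.

    Computed (not measured) so chunk boundaries are deterministic and
    platform independent: each string column contributes its UTF-8 length
    plus one 4-byte offset per row; each integer column contributes 4
    bytes.
    """
    n = batch.num_rows
    total = np.full(n, _INT_WIDTH * len(_INT_FIELDS), dtype=np.int64)
    for name in SAM_FIELDS:
        if name in _INT_FIELDS:
            continue
        col = batch.column(name)
        # byte length per value from the arrow offsets buffer
        lengths = pa.compute.binary_length(col).to_numpy(zero_copy_only=False)
        total += lengths.astype(np.int64) + _OFFSET_WIDTH
    return total


def approx_batch_bytes(batch: ReadBatch) -> int:
    """Estimated size of a whole batch (row bytes + one closing offset per
    string column)."""
    n_string_cols = len(SAM_FIELDS) - len(_INT_FIELDS)
    if batch.num_rows == 0:
        return n_string_cols * _OFFSET_WIDTH
    return int(approx_row_bytes(batch).sum()) + n_string_cols * _OFFSET_WIDTH


# ---------------------------------------------------------------------------
# Chunk / Partition
# ---------------------------------------------------------------------------


@dataclass
class Chunk:
    """A contiguous, bounded-size run of one chromosome's reads.

    ``batch`` holds the rows this chunk *owns*; ``pad_left``/``pad_right``
    hold read-only copies of neighbour rows whose positions fall within
    the configured padding window of the chunk's cut points.  Padding rows
    take part in window-local computations but never receive outputs —
    their owning chunk decides them.
    """

    batch: ReadBatch
    chrom: str
    ordinal: int = 0
    sorted: bool = False
    pad_left: ReadBatch = field(default_factory=ReadBatch.empty)
    pad_right: ReadBatch = field(default_factory=ReadBatch.empty)

    payload_kind = "chunk"

    @property
    def num_rows(self) -> int:
        """Owned rows only (padding excluded)."""
        return self.batch.num_rows

    @property
    def pos_span(self) -> tuple[int, int]:
        if self.batch.num_rows == 0:
            return (0, 0)
        pos = self.batch.ints("pos")
        return (int(pos.min()), int(pos.max()))

    @property
    def approx_bytes(self) -> int:
        return approx_batch_bytes(self.batch)

    def combined(self) -> tuple[ReadBatch, int, int]:
        """(padding+owned rows, owned start, owned stop) as one batch."""
        nl = self.pad_left.num_rows
        combined = concat_batches([self.pad_left, self.batch, self.pad_right])
        return combined, nl, nl + self.batch.num_rows

    def check(self) -> None:
        """Raise on a broken chunk invariant."""
        if self.chrom != "*":
            for i, rn in enumerate(self.batch.strings("rname")):
                if rn != self.chrom:
                    raise ColsamError(
                        f"row {i} has rname {rn!r}, expected {self.chrom!r}")
        if self.sorted and self.batch.num_rows > 1:
            pos = self.batch.ints("pos")
            if np.any(np.diff(pos) < 0):
                raise ColsamError(f"chunk {self.chrom}/{self.ordinal} marked "
                                  "sorted but pos is decreasing")

    # -- store payload codec ----------------------------------------------
    def to_record_batch(self) -> pa.RecordBatch:
        combined, start, stop = self.combined()
        meta = {
            b"colsam_kind": b"chunk",
            b"chrom": self.chrom.encode(),
            b"ordinal": str(self.ordinal).encode(),
            b"sorted": b"1" if self.sorted else b"0",
            b"n_pad_left": str(self.pad_left.num_rows).encode(),
            b"n_pad_right": str(self.pad_right.num_rows).encode(),
        }
        return combined.data.replace_schema_metadata(meta)

    @classmethod
    def from_record_batch(cls, rb: pa.RecordBatch) -> "Chunk":
        meta = rb.schema.metadata or {}
        nl = int(meta.get(b"n_pad_left", b"0"))
        nr = int(meta.get(b"n_pad_right", b"0"))
        clean = rb.replace_schema_metadata(None)
        n = rb.num_rows
        return cls(
            batch=ReadBatch(clean.slice(nl, n - nl - nr)),
            chrom=meta[b"chrom"].decode(),
            ordinal=int(meta[b"ordinal"]),
            sorted=meta.get(b"sorted", b"0") == b"1",
            pad_left=ReadBatch(clean.slice(0, nl)),
            pad_right=ReadBatch(clean.slice(n - nr, nr)),
        )


@dataclass
class Partition:
    """One chromosome's reads as an ordered list of chunks."""

    chrom: str
    chunks: list[Chunk] = field(default_factory=list)

    @property
    def num_rows(self) -> int:
        return sum(c.num_rows for c in self.chunks)

    def check(self) -> None:
        for expected, chunk in enumerate(self.chunks):
            if chunk.ordinal != expected:
                raise ColsamError(
                    f"chunk ordinals not consecutive: got {chunk.ordinal}, "
                    f"expected {expected}")
            if chunk.chrom != self.chrom:
                raise ColsamError(
                    f"chunk chrom {chunk.chrom!r} != partition {self.chrom!r}")
            chunk.check()
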