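"""SAM and BED text I/O.

Parsing is deliberately byte-faithful: mandatory fields become typed
columns, every optional field is kept verbatim in the ``tags`` column,
and :func:`write_sam` re-emits exactly the bytes :func:`read_sam` saw.
This keeps the columnar representation a lossless stand-in for the SAM
file, so external tools can be fed the exported text at any stage.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .model import ReadBatch, SamHeader, SamParseError

__all__ = ["read_sam", "write_sam", "sam_lines", "read_bed", "IntervalSet"]


def _open_text(source, mode: str):
    if isinstance(source, (str, os.PathLike)):
        return open(source, mode, encoding="utf-8", newline=""), True
    return source, False


_INT_FIELD_POS = {"flag": 1, "pos": 3, "mapq": 4, "pnext": 7, "tlen": 8}


def read_sam(source) -> tuple[SamHeader, ReadBatch]:
    """Parse SAM text into a header and a columnar read batch.

    ``source`` is a path or an open text stream.  Header lines are kept
    verbatim; alignment line *i* becomes batch row *i*; fields beyond the
    11 mandatory ones are tab-joined into the ``tags`` column (empty
    string when absent).
    """
    stream, close = _open_text(source, "r")
    try:
        header_lines: list[str] = []
        cols: dict[str, list] = {
            "qname": [], "flag": [], "rname": [], "pos": [], "mapq": [],
            "cigar": [], "rnext": [], "pnext": [], "tlen": [],
            "seq": [], "qual": [], "tags": [],
        }
        in_header = True
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if in_header and line.startswith("@"):
                header_lines.append(line)
                continue
            in_header = False
            fields = line.split("\t", 11)
            if len(fields) < 11:
                raise SamParseError(
                    f"alignment line has {len(fields)} fields, expected >= 11",
                    lineno)
            for name, j in _INT_FIELD_POS.items():
                try:
                    cols[name].append(int(fields[j]))
                except ValueError:
                    raise SamParseError(
                        f"non-integer {name.upper()} field: {fields[j]!r}",
                        lineno)
            cols["qname"].append(fields[0])
            cols["rname"].append(fields[2])
            cols["cigar"].append(fields[5])
            cols["rnext"].append(fields[6])
            cols["seq"].append(fields[9])
            cols["qual"].append(fields[10])
            cols["tags"].append(fields[11] if len(fields) > 11 else "")
        header = SamHeader.parse(header_lines)
        return header, ReadBatch.from_pydict(cols)
    finally:
        if close:
            stream.close()


def sam_lines(batch: ReadBatch) -> Iterator[str]:
    """Yield one SAM alignment line (without newline) per batch row."""
    columns = [batch.strings(n) if n not in _INT_FIELD_POS
               else [str(v) for v in batch.ints(n)]
               for n in ("qname", "flag", "rname", "pos", "mapq", "cigar",
                         "rnext", "pnext", "tlen", "seq", "qual", "tags")]
    for row in zip(*columns):
        base = "\t".join(row[:11])
        yield base + "\t" + row[11] if row[11] else base


def write_sam(header: SamHeader, batch: ReadBatch, sink) -> int:
    """Serialize header + batch as SAM text; returns rows written.

    Inverse of :func:`read_sam`: the emitted alignment lines are
    byte-identical to the parsed input.
    """
    stream, close = _open_text(sink, "w")
    try:
        stream.write(header.serialize())
        n = 0
        for line in sam_lines(batch):
            stream.write(line)
            stream.write("\n")
            n += 1
        return n
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------


@dataclass
class IntervalSet:
    """Merged, sorted genomic intervals (0-based, half-open as in BED).

    Overlapping or adjacent intervals on the same chromosome are merged
    on construction; downstream only membership matters, so merging is
    lossless for filtering purposes.
    """

    intervals: list[tuple[str, int, int]] = field(default_factory=list)
    _by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False, compare=False)

    @classmethod
    def from_raw(cls, raw: list[tuple[str, int, int]]) -> "IntervalSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in raw:
            by_chrom.setdefault(chrom, []).append((start, end))
        merged: list[tuple[str, int, int]] = []
        for chrom in sorted(by_chrom):
            spans = sorted(by_chrom[chrom])
            cur_s, cur_e = spans[0]
            for s, e in spans[1:]:
                if s <= cur_e:          # overlap or adjacency: merge
                    cur_e = max(cur_e, e)
                else:
                    merged.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((chrom, cur_s, cur_e))
        return cls(merged)

    def __post_init__(self):
        self._by_chrom = {}
        for chrom, start, end in self.intervals:
            self._by_chrom.setdefault(chrom, ([], []))
            self._by_chrom[chrom][0].append(start)
            self._by_chrom[chrom][1].append(end)
        self._by_chrom = {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for c, (s, e) in self._by_chrom.items()
        }

    def __len__(self) -> int:
        return len(self.intervals)

    def for_chrom(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays for one chromosome (possibly empty)."""
        empty = np.empty(0, dtype=np.int64)
        return self._by_chrom.get(chrom, (empty, empty))


def read_bed(source) -> IntervalSet:
    """Parse BED3+ text into a merged :class:`IntervalSet`.

    ``track``/``browser``/``#`` lines are skipped; only the first three
    columns are used.
    """
    stream, close = _open_text(source, "r")
    raw: list[tuple[str, int, int]] = []
    try:
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if (not line or line.startswith("#")
                    or line.startswith("track") or line.startswith("browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            if len(fields) < 3:
                raise SamParseError(
                    f"BED line has {len(fields)} columns, expected >= 3", lineno)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise SamParseError(
                    f"non-integer BED coordinate on {chrom}", lineno)
            if start < 0:
                raise SamParseError(f"negative BED start {start}", lineno)
            if end <= start:
                raise SamParseError(
                    f"BED end {end} <= start {start}", lineno)
            raw.append((chrom, start, end))
    finally:
        if close:
            stream.close()
    return IntervalSet.from_raw(raw)
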