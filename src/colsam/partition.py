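"""Per-chromosome routing and chunking of read batches.

Ingest routes every read to its chromosome's partition (reads with
``rname == '*'`` go to a reserved unmapped partition that bypasses
sorting and duplicate marking).  A sorted partition whose estimated size
exceeds ``max_bytes`` is split into chunks; cut points fall only between
rows with different positions, and each chunk carries padding rows
copied from its neighbourhood within ``pad_bp`` of the cut so that
window-local stages see complete candidate groups across boundaries.
"""

from __future__ import annotations

import logging

import numpy as np

from .model import (
    Chunk,
    ColsamError,
    Partition,
    ReadBatch,
    SamHeader,
    approx_row_bytes,
    concat_batches,
    slice_rows,
)

__all__ = ["partition_by_chrom", "split_partition", "DEFAULT_MAX_BYTES",
           "DEFAULT_PAD_BP"]

logger = logging.getLogger(__name__)

#: Default chunking threshold: partitions above this estimated size are
#: split so each shared object stays bounded.
DEFAULT_MAX_BYTES = 2 * 1024 ** 3

#: Default boundary padding in base pairs.  Must be at least the maximum
#: template span (for paired data) plus clip length for duplicate-group
#: decisions to be independent of chunk boundaries.
DEFAULT_PAD_BP = 1000


def partition_by_chrom(header: SamHeader, batch: ReadBatch) -> dict[str, ReadBatch]:
    """Split a batch into per-chromosome batches, preserving row order.

    Returns a mapping in header reference order (only chromosomes that
    occur), with the unmapped ``'*'`` partition last when present.
    Every input row appears in exactly one output batch.
    """
    rnames = batch.strings("rname")
    known = set(header.references)
    by_chrom: dict[str, list[int]] = {}
    for i, rn in enumerate(rnames):
        if rn != "*" and rn not in known:
            raise ColsamError(
                f"rname {rn!r} at row {i} is not in the header references")
        by_chrom.setdefault(rn, []).append(i)
    out: dict[str, ReadBatch] = {}
    for chrom in header.references:
        if chrom in by_chrom:
            out[chrom] = slice_rows(batch, by_chrom[chrom])
    if "*" in by_chrom:
        out["*"] = slice_rows(batch, by_chrom["*"])
    return out


def _greedy_cuts(pos: np.ndarray, row_bytes: np.ndarray,
                 max_bytes: int) -> list[tuple[int, int]]:
    """Pack position groups into chunks of at most ``max_bytes``.

    Returns (start, stop) row ranges.  A cut may only fall between rows
    with different ``pos``; a single position group larger than
    ``max_bytes`` becomes one oversized chunk (warned, not split).
    """
    n = len(pos)
    # start indices of runs of equal pos
    group_starts = np.concatenate(
        ([0], np.flatnonzero(np.diff(pos) != 0) + 1, [n]))
    ranges: list[tuple[int, int]] = []
    cur_start = 0
    cur_bytes = 0
    for gi in range(len(group_starts) - 1):
        g0, g1 = int(group_starts[gi]), int(group_starts[gi + 1])
        g_bytes = int(row_bytes[g0:g1].sum())
        if cur_bytes > 0 and cur_bytes + g_bytes > max_bytes:
            ranges.append((cur_start, g0))
            cur_start, cur_bytes = g0, 0
        cur_bytes += g_bytes
        if cur_bytes > max_bytes:
            if g0 != cur_start:
                # flush what was accumulated before the oversized group
                ranges.append((cur_start, g0))
                cur_start = g0
            logger.warning(
                "position group at pos=%d (%d rows, ~%d bytes) exceeds "
                "max_bytes=%d; emitting one oversized chunk",
                int(pos[g0]), g1 - g0, g_bytes, max_bytes)
            ranges.append((g0, g1))
            cur_start, cur_bytes = g1, 0
    if cur_start < n:
        ranges.append((cur_start, n))
    return ranges


def split_partition(partition: Partition,
                    max_bytes: int | None = DEFAULT_MAX_BYTES,
                    pad_bp: int = DEFAULT_PAD_BP) -> Partition:
    """Split a sorted partition into bounded-size chunks with padding.

    The concatenation of the output chunks' owned rows equals the input
    batch exactly; padding rows are copies and carry no ownership.
    """
    batch = concat_batches([c.batch for c in partition.chunks])
    if batch.num_rows == 0:
        return Partition(partition.chrom, [Chunk(
            batch, partition.chrom, 0, sorted=True)])
    pos = batch.ints("pos")
    if np.any(np.diff(pos) < 0):
        raise ColsamError(
            f"partition {partition.chrom!r} must be coordinate-sorted "
            "before splitting")
    total = None
    if max_bytes is not None:
        row_bytes = approx_row_bytes(batch)
        total = int(row_bytes.sum())
    if max_bytes is None or total <= max_bytes:
        return Partition(partition.chrom, [Chunk(
            batch, partition.chrom, 0, sorted=True)])

    ranges = _greedy_cuts(pos, row_bytes, max_bytes)
    chunks: list[Chunk] = []
    for ordinal, (start, stop) in enumerate(ranges):
        # padding: all rows (owned by any neighbour chunk) whose pos is
        # within pad_bp of this chunk's cut positions
        lo = int(np.searchsorted(pos, pos[start] - pad_bp, side="left"))
        hi = int(np.searchsorted(pos, pos[stop - 1] + pad_bp, side="right"))
        lo = min(lo, start)
        hi = max(hi, stop)
        chunks.append(Chunk(
            batch=ReadBatch(batch.data.slice(start, stop - start)),
            chrom=partition.chrom,
            ordinal=ordinal,
            sorted=True,
            pad_left=ReadBatch(batch.data.slice(lo, start - lo)),
            pad_right=ReadBatch(batch.data.slice(stop, hi - stop)),
        ))
    return Partition(partition.chrom, chunks)
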