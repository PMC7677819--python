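"""Coordinate sorting of per-chromosome partitions.

Each chromosome is sorted independently by leftmost mapping position
(``pos``), with ties broken by input order (stable sort) — so outputs
are identical for any worker count or completion order.  Sorting runs
over whole chromosomes first; chunking of oversized partitions happens
afterwards, because chunk boundaries require sorted positions.  The
reserved unmapped partition passes through unsorted.
"""

from __future__ import annotations

import logging
from multiprocessing import get_context

import numpy as np

from .model import Chunk, ColsamError, Partition, concat_batches, slice_rows
from .partition import DEFAULT_PAD_BP, split_partition
from .store import ObjectKey, ObjectStore

__all__ = ["sort_partition", "sort_all"]

logger = logging.getLogger(__name__)


def sort_partition(partition: Partition) -> Partition:
    """Stable-sort one partition's reads by position.

    Output rows are a permutation of the input; rows with equal ``pos``
    keep their input relative order.  Reads with ``pos == 0`` inside a
    named chromosome sort first (they precede ``pos >= 1`` numerically).
    """
    batch = concat_batches([c.batch for c in partition.chunks])
    if batch.num_rows:
        rnames = set(batch.strings("rname"))
        if len(rnames) > 1:
            raise ColsamError(
                f"partition {partition.chrom!r} mixes rnames {sorted(rnames)}")
    pos = batch.ints("pos")
    if batch.num_rows > 1 and np.any(np.diff(pos) < 0):
        order = np.argsort(pos, kind="stable")
        batch = slice_rows(batch, order)
    return Partition(partition.chrom,
                     [Chunk(batch, partition.chrom, 0, sorted=True)])


def _sort_chrom(args) -> tuple[str, int, int]:
    (root, in_namespace, out_namespace, chrom, ordinals,
     max_bytes, pad_bp) = args
    store = ObjectStore(root)
    chunks = [store.get(ObjectKey(in_namespace, chrom, o)) for o in ordinals]
    partition = Partition(chrom, [c for c in chunks])
    if chrom == "*":
        # unmapped reads bypass sorting; single pass-through chunk
        batch = concat_batches([c.batch for c in chunks])
        out = Partition("*", [Chunk(batch, "*", 0, sorted=False)])
    else:
        out = split_partition(sort_partition(partition),
                              max_bytes=max_bytes, pad_bp=pad_bp)
    for chunk in out.chunks:
        store.put(ObjectKey(out_namespace, chrom, chunk.ordinal), chunk)
    return chrom, out.num_rows, len(out.chunks)


def sort_all(store: ObjectStore,
             in_namespace: str = "aligned",
             out_namespace: str = "sorted",
             workers: int = 1,
             max_bytes: int | None = None,
             pad_bp: int = DEFAULT_PAD_BP,
             delete_input: bool = True) -> dict[str, int]:
    """Sort every chromosome in the store, chromosome-parallel.

    Writes one sorted (and, above ``max_bytes``, chunked) object per
    (chromosome, ordinal) into ``out_namespace``; the input namespace is
    dropped afterwards when ``delete_input`` is set.  Returns per-
    chromosome row counts in header order.
    """
    keys = store.list_keys(in_namespace)
    by_chrom: dict[str, list[int]] = {}
    for k in keys:
        by_chrom.setdefault(k.chrom, []).append(k.ordinal)
    tasks = [
        (store.root, in_namespace, out_namespace, chrom, sorted(ordinals),
         max_bytes, pad_bp)
        for chrom, ordinals in by_chrom.items()
    ]
    results = _run_tasks(_sort_chrom, tasks, workers)
    summary = {chrom: nrows for chrom, nrows, _ in results}
    rank = store._chrom_rank()
    summary = dict(sorted(summary.items(),
                          key=lambda kv: (rank.get(kv[0], len(rank)), kv[0])))
    if delete_input:
        store.drop_namespace(in_namespace)
    logger.info("sorted %d chromosomes, %d rows",
                len(summary), sum(summary.values()))
    return summary


def _run_tasks(fn, tasks, workers: int):
    """Map ``fn`` over tasks, optionally with a process pool.

    Results are collected in task order, so output is independent of
    completion order.
    """
    if workers <= 1 or len(tasks) <= 1:
        return [fn(t) for t in tasks]
    ctx = get_context("fork")
    with ctx.Pool(min(workers, len(tasks))) as pool:
        return pool.map(fn, tasks)
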