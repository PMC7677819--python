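"""Duplicate marking on the columnar representation.

Reads (or read pairs) that share the same unclipped 5′ end(s) and
orientation(s) are duplicates of each other: they are PCR or optical
copies of one original fragment.  Within each duplicate group the
highest-scoring member survives and every other member gets FLAG bit
0x400 set.  The stage's output is not a rewritten batch but a *FLAG
delta* — a replacement FLAG column per chunk — so downstream stages keep
reading the sorted objects and overlay the new flags.

Grouping geometry
-----------------
The grouping coordinate of a read is its unclipped 5′ end on the
sequencing strand: the leftmost mapping position minus leading soft/hard
clips for a forward read, or the rightmost reference position plus
trailing clips for a reverse read.  For paired reads the key combines
both ends, ordered canonically so that both mates — processed
independently, possibly in different partitions — compute the same key.
The mate's unclipped end is derived from the MC (mate CIGAR) tag when
present; otherwise PNEXT is used without clip correction and a warning
counter is kept.

Scoring
-------
``sum_of_base_qualities``: sum of Phred values >= 15 over the read's
bases (summed over both mates when both are visible) — the conventional
default.  ``total_mapped_length``: query bases consumed by M/=/X, for
data without usable base qualities.  Ties break deterministically by
(score descending, qname ascending).

Unpaired reads whose end coincides with a paired group's end are marked
as duplicates of the pair regardless of score (a fragment never outranks
a pair).  Secondary, supplementary and unmapped records are never
candidates and never marked.

Chunks include their boundary padding rows during grouping so decisions
match an unpartitioned run, but flags are emitted only for owned rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pyarrow as pa

from .model import (
    FLAG_DUPLICATE,
    FLAG_MATE_REVERSE,
    FLAG_MATE_UNMAPPED,
    FLAG_PAIRED,
    FLAG_REVERSE,
    FLAG_SECONDARY,
    FLAG_SUPPLEMENTARY,
    FLAG_UNMAPPED,
    Chunk,
    ColsamError,
    cigar_reference_span,
    leading_clip,
    parse_cigar,
    trailing_clip,
)
from .store import ObjectKey, ObjectStore

__all__ = ["unclipped_5p", "duplicate_score", "FlagDelta",
           "mark_duplicates_chunk", "mark_duplicates_all",
           "SCORING_STRATEGIES"]

logger = logging.getLogger(__name__)

SCORING_STRATEGIES = ("sum_of_base_qualities", "total_mapped_length")

_BASEQ_MIN = 15  # Phred values below this do not count toward the score


def unclipped_5p(pos: int, cigar: str, strand: str) -> int:
    """Unclipped 5′ end of an alignment on its sequencing strand.

    Forward: ``pos`` minus leading soft/hard clips.  Reverse: rightmost
    reference position (``pos`` + reference span − 1) plus trailing
    clips.
    """
    if cigar == "*":
        raise ColsamError("unclipped_5p needs a real CIGAR, got '*'")
    if pos < 1:
        raise ColsamError(f"unclipped_5p needs pos >= 1, got {pos}")
    if strand == "F":
        return pos - leading_clip(cigar)
    if strand == "R":
        return pos + cigar_reference_span(cigar) - 1 + trailing_clip(cigar)
    raise ColsamError(f"strand must be 'F' or 'R', got {strand!r}")


def duplicate_score(seq: str, qual: str, strategy: str,
                    cigar: str = "*") -> int:
    """Score one read for survivor selection within a duplicate group."""
    if strategy == "sum_of_base_qualities":
        if qual == "*":
            raise ColsamError(
                "sum_of_base_qualities scoring needs base qualities, "
                "got qual='*'")
        return sum(q - 33 for q in qual.encode("ascii") if q - 33 >= _BASEQ_MIN)
    if strategy == "total_mapped_length":
        return sum(n for n, op in parse_cigar(cigar) if op in "M=X")
    raise ColsamError(f"unknown scoring strategy {strategy!r}; "
                      f"expected one of {SCORING_STRATEGIES}")


@dataclass
class FlagDelta:
    """Replacement FLAG column for one chunk's owned rows.

    Differs from the source flags only in bit 0x400.
    """

    flags: np.ndarray
    key: ObjectKey | None = None
    mate_cigar_missing: int = 0   # reads scored without an MC tag

    payload_kind = "flagdelta"

    def __len__(self) -> int:
        return len(self.flags)

    def to_record_batch(self) -> pa.RecordBatch:
        meta = {b"colsam_kind": b"flagdelta",
                b"mate_cigar_missing": str(self.mate_cigar_missing).encode()}
        return pa.record_batch(
            [pa.array(self.flags, type=pa.int32())], names=["flag"]
        ).replace_schema_metadata(meta)

    @classmethod
    def from_record_batch(cls, rb: pa.RecordBatch) -> "FlagDelta":
        meta = rb.schema.metadata or {}
        return cls(
            flags=rb.column(0).to_numpy(zero_copy_only=False).astype(np.int64),
            mate_cigar_missing=int(meta.get(b"mate_cigar_missing", b"0")),
        )


def _mate_cigar(tags: str) -> str | None:
    if "MC:Z:" not in tags:
        return None
    for t in tags.split("\t"):
        if t.startswith("MC:Z:"):
            return t[5:]
    return None


def mark_duplicates_chunk(chunk: Chunk, scoring: str = "sum_of_base_qualities",
                          ) -> FlagDelta:
    """Mark duplicates within one chunk (padding rows included in the
    grouping, excluded from the output)."""
    if not chunk.sorted and chunk.chrom != "*":
        raise ColsamError(
            f"chunk {chunk.chrom}/{chunk.ordinal} must be sorted before "
            "duplicate marking")
    combined, owned_start, owned_stop = chunk.combined()
    n = combined.num_rows
    flags = combined.ints("flag")
    pos = combined.ints("pos")
    pnext = combined.ints("pnext")
    rname = combined.strings("rname")
    rnext = combined.strings("rnext")
    cigar = combined.strings("cigar")
    seq = combined.strings("seq")
    qual = combined.strings("qual")
    qname = combined.strings("qname")
    tags = combined.strings("tags")

    mc_missing = 0
    # unit_members: canonical pair key -> {qname -> [row, ...]}
    pair_groups: dict[tuple, dict[str, list[int]]] = {}
    frag_groups: dict[tuple, list[int]] = {}
    paired_ends: set[tuple] = set()
    scores = np.zeros(n, dtype=np.int64)

    for i in range(n):
        f = int(flags[i])
        if f & (FLAG_UNMAPPED | FLAG_SECONDARY | FLAG_SUPPLEMENTARY):
            continue
        if cigar[i] == "*" or pos[i] < 1:
            continue
        strand = "R" if f & FLAG_REVERSE else "F"
        end = (rname[i], unclipped_5p(int(pos[i]), cigar[i], strand), strand)
        scores[i] = duplicate_score(seq[i], qual[i], scoring, cigar[i])
        if (f & FLAG_PAIRED) and not (f & FLAG_MATE_UNMAPPED):
            mate_chrom = rname[i] if rnext[i] == "=" else rnext[i]
            mate_strand = "R" if f & FLAG_MATE_REVERSE else "F"
            mc = _mate_cigar(tags[i])
            if mc is not None:
                mate_u5p = unclipped_5p(int(pnext[i]), mc, mate_strand)
            else:
                mate_u5p = int(pnext[i])
                mc_missing += 1
            mate_end = (mate_chrom, mate_u5p, mate_strand)
            key = (min(end, mate_end), max(end, mate_end))
            pair_groups.setdefault(key, {}).setdefault(qname[i], []).append(i)
            paired_ends.add(end)
        else:
            frag_groups.setdefault(end, []).append(i)

    marked = np.zeros(n, dtype=bool)
    decided = np.zeros(n, dtype=bool)

    for key, units in pair_groups.items():
        rows_in_group = [r for rows in units.values() for r in rows]
        for r in rows_in_group:
            decided[r] = True
        if len(units) < 2:
            continue
        # unit score: sum over the unit's visible reads
        ranked = sorted(
            units.items(),
            key=lambda kv: (-int(sum(scores[r] for r in kv[1])), kv[0]))
        for _, rows in ranked[1:]:
            for r in rows:
                marked[r] = True

    for end, rows in frag_groups.items():
        for r in rows:
            decided[r] = True
        if end in paired_ends:
            # a fragment at a pair's 5' end duplicates the pair
            for r in rows:
                marked[r] = True
            continue
        if len(rows) < 2:
            continue
        ranked = sorted(rows, key=lambda r: (-int(scores[r]), qname[r]))
        for r in ranked[1:]:
            marked[r] = True

    out = flags[owned_start:owned_stop].copy()
    owned_decided = decided[owned_start:owned_stop]
    owned_marked = marked[owned_start:owned_stop]
    out[owned_decided] &= ~FLAG_DUPLICATE
    out[owned_marked] |= FLAG_DUPLICATE
    if mc_missing:
        logger.warning(
            "chunk %s/%d: %d paired reads scored without an MC tag "
            "(mate end taken from PNEXT, no clip correction)",
            chunk.chrom, chunk.ordinal, mc_missing)
    return FlagDelta(flags=out, mate_cigar_missing=mc_missing)


def _markdup_task(args) -> tuple[str, int, int]:
    root, in_namespace, out_namespace, chrom, ordinal, scoring = args
    store = ObjectStore(root)
    chunk = store.get(ObjectKey(in_namespace, chrom, ordinal))
    if chrom == "*":
        delta = FlagDelta(flags=chunk.batch.ints("flag").copy())
    else:
        delta = mark_duplicates_chunk(chunk, scoring=scoring)
    src = chunk.batch.ints("flag")
    n_marked = int(np.sum((delta.flags & FLAG_DUPLICATE).astype(bool)
                          & ~(src & FLAG_DUPLICATE).astype(bool)))
    store.put(ObjectKey(out_namespace, chrom, ordinal), delta)
    return chrom, ordinal, n_marked


def mark_duplicates_all(store: ObjectStore,
                        workers: int = 1,
                        scoring: str = "sum_of_base_qualities",
                        in_namespace: str = "sorted",
                        out_namespace: str = "flagdelta") -> dict[str, int]:
    """Mark duplicates over every sorted chunk, chunk-parallel.

    Writes one FLAG delta per chunk; returns newly-marked counts per
    chromosome (bit 0x400 transitions 0 -> 1), in header order.
    """
    keys = store.list_keys(in_namespace)
    if not keys:
        raise ColsamError(f"no objects in namespace {in_namespace!r}")
    tasks = [(store.root, in_namespace, out_namespace, k.chrom, k.ordinal,
              scoring) for k in keys]
    from .sort import _run_tasks
    results = _run_tasks(_markdup_task, tasks, workers)
    summary: dict[str, int] = {}
    for chrom, _, n_marked in results:
        summary[chrom] = summary.get(chrom, 0) + n_marked
    rank = store._chrom_rank()
    summary = dict(sorted(summary.items(),
                          key=lambda kv: (rank.get(kv[0], len(rank)), kv[0])))
    logger.info("marked %d duplicate reads over %d chunks",
                sum(summary.values()), len(keys))
    return summary
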