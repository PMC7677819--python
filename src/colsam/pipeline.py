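"""End-to-end orchestration: ingest → sort → chunk → markdup →
interval filter / quality update → export.

All inter-stage data passes through the object store; stages only ever
exchange chunk and delta objects.  Worker pools are per-chunk with
deterministic collation by (chromosome header order, ordinal), so the
exported SAM is byte-identical for any worker count.
"""

from __future__ import annotations

import logging
import tempfile
import time
from dataclasses import dataclass, fields, replace
from pathlib import Path

import numpy as np
import yaml

from . import markdup as _markdup
from . import views as _views
from .model import ColsamError, SamHeader
from .partition import DEFAULT_PAD_BP, partition_by_chrom
from .samio import read_bed, read_sam, write_sam
from .simulate import SimSpec, simulate
from .sort import sort_all
from .store import ObjectKey, ObjectStore

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


def _parse_transform(spec: str):
    """Quality transform spec: 'identity' or 'shift:<delta>' (e.g.
    'shift:+2'); values outside Phred 0..93 raise at application time."""
    if spec == "identity":
        return lambda q: q
    if spec.startswith("shift:"):
        delta = int(spec.split(":", 1)[1])
        return lambda q: q + delta
    raise ColsamError(f"unknown quality transform {spec!r}")


@dataclass
class PipelineConfig:
    """Everything a run needs; mirrors the CLI flags and the YAML config
    file (CLI overrides file values)."""

    input_sam: str | None = None          #: path to input SAM
    simulate: dict | None = None          #: SimSpec overrides instead of a file
    bed: str | None = None                #: optional interval filter
    out: str | None = None                #: exported SAM path (or dir)
    store_dir: str | None = None          #: object store location (tmp if None)
    workers: int = 1
    max_bytes: int | None = None          #: chunking threshold (None = single chunk)
    pad_bp: int = DEFAULT_PAD_BP
    scoring: str = "sum_of_base_qualities"
    qual_transform: str = "identity"
    duplicate_marking: bool = True
    keep_intermediate: bool = False       #: keep pre-sort objects
    per_chrom_out: bool = False
    debug_dump: str | None = None         #: directory for per-stage SAM snapshots
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ColsamError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        overrides = {k: v for k, v in overrides.items() if v is not None}
        return replace(cfg, **overrides)


def _ingest(cfg: PipelineConfig, store: ObjectStore) -> tuple[SamHeader, dict]:
    from .model import Chunk
    if cfg.input_sam:
        header, batch = read_sam(cfg.input_sam)
    elif cfg.simulate is not None:
        sim = simulate(SimSpec(seed=cfg.seed), **cfg.simulate)
        header, batch = sim.header, sim.batch
    else:
        raise ColsamError("config must name an input SAM or a simulator spec")
    store.set_header(header)
    parts = partition_by_chrom(header, batch)
    for chrom, part_batch in parts.items():
        store.put(ObjectKey("aligned", chrom, 0),
                  Chunk(part_batch, chrom, 0, sorted=False))
    return header, {chrom: b.num_rows for chrom, b in parts.items()}


def _dump_stage(store: ObjectStore, header: SamHeader, dump_dir: str,
                stage: str) -> None:
    from .model import concat_batches
    outdir = Path(dump_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    keys = store.list_keys("sorted") or store.list_keys("aligned")
    batches = [store.get(k).batch for k in keys]
    write_sam(header, concat_batches(batches), outdir / f"{stage}.sam")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all configured stages; returns the run report.

    The report carries per-stage row counts, per-chromosome duplicate
    counts, the final object inventory and a conservation check
    (ingested == exported + filtered-out).
    """
    t0 = time.monotonic()
    tmp = None
    if cfg.store_dir is None:
        tmp = tempfile.TemporaryDirectory(prefix="colsam-store-")
        store_dir = tmp.name
    else:
        store_dir = cfg.store_dir
    try:
        store = ObjectStore(store_dir)
        report: dict = {"stages": {}}

        def stage(name):
            t = time.monotonic()

            def done(**counts):
                report["stages"][name] = {
                    "seconds": round(time.monotonic() - t, 3), **counts}
                logger.info("stage %-8s %.2fs %s", name,
                            time.monotonic() - t, counts)
            return done

        end = stage("ingest")
        header, part_counts = _ingest(cfg, store)
        report["input_reads"] = sum(part_counts.values())
        report["partitions"] = part_counts
        end(reads=report["input_reads"], partitions=len(part_counts))
        if cfg.debug_dump:
            _dump_stage(store, header, cfg.debug_dump, "ingest")

        end = stage("sort")
        sort_summary = sort_all(
            store, workers=cfg.workers, max_bytes=cfg.max_bytes,
            pad_bp=cfg.pad_bp, delete_input=not cfg.keep_intermediate)
        report["sorted_reads"] = sum(sort_summary.values())
        report["chunks"] = len(store.list_keys("sorted"))
        end(reads=report["sorted_reads"], chunks=report["chunks"])
        if cfg.debug_dump:
            _dump_stage(store, header, cfg.debug_dump, "sorted")

        if cfg.duplicate_marking:
            end = stage("markdup")
            dup_summary = _markdup.mark_duplicates_all(
                store, workers=cfg.workers, scoring=cfg.scoring)
            report["duplicates_marked"] = dup_summary
            report["duplicates_total"] = sum(dup_summary.values())
            end(duplicates=report["duplicates_total"])
        else:
            report["duplicates_marked"] = {}
            report["duplicates_total"] = 0

        filtered_out = 0
        if cfg.bed:
            end = stage("filter")
            intervals = read_bed(cfg.bed)
            transform = _parse_transform(cfg.qual_transform)
            for key in store.list_keys("sorted"):
                chunk = store.get(key)
                idx = _views.filter_by_intervals(chunk, intervals)
                delta = _views.apply_qual_transform(chunk, idx, transform)
                store.put(ObjectKey("qualindex", key.chrom, key.ordinal),
                          delta)
                filtered_out += chunk.num_rows - len(idx)
            end(intervals=len(intervals), filtered_out=filtered_out)
        report["filtered_out"] = filtered_out

        exported = 0
        if cfg.out:
            end = stage("export")
            exported = _views.export_final(
                store, header, cfg.out, per_chrom=cfg.per_chrom_out)
            end(reads=exported)
        report["exported"] = exported

        report["objects"] = store.inventory()
        report["store_bytes"] = store.total_bytes()
        if cfg.out:
            report["conservation_ok"] = (
                report["input_reads"] == exported + filtered_out)
        report["total_seconds"] = round(time.monotonic() - t0, 3)
        return report
    finally:
        if tmp is not None:
            tmp.cleanup()
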