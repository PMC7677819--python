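"""Stage projections, interval filtering, delta resolution and export."""

import io

import numpy as np
import pytest

from colsam.markdup import FlagDelta
from colsam.model import Chunk, ColsamError, Partition, slice_rows
from colsam.partition import partition_by_chrom
from colsam.samio import IntervalSet, read_sam
from colsam.sort import sort_all, sort_partition
from colsam.store import ObjectKey, ObjectStore
from colsam.views import (
    QualIndexDelta,
    apply_qual_transform,
    export_final,
    filter_by_intervals,
    resolve_reads,
    stage_view,
)

from conftest import make_batch


def chunk100(pos_list, chrom="chr1"):
    rows = [{"pos": p, "rname": chrom, "cigar": "100M", "seq": "A" * 100,
             "qual": "I" * 100, "qname": f"r{i}"}
            for i, p in enumerate(pos_list)]
    return Chunk(make_batch(rows), chrom, 0, sorted=True)


class TestStageView:
    def test_markdup_view_exposes_exactly_its_six_fields(self):
        view = stage_view(chunk100([10]), "markdup")
        assert view.names() == ("QNAME", "FLAG", "RNAME", "POS", "CIGAR",
                                "RNEXT")

    def test_bqsr_view_exposes_seven_fields_with_delta_flags(self):
        chunk = chunk100([10, 20])
        delta = FlagDelta(flags=np.array([0x400, 0]))
        view = stage_view(chunk, "bqsr", flag_delta=delta)
        assert view.names() == ("RNAME", "POS", "MAPQ", "CIGAR", "SEQ",
                                "QUAL", "FLAG")
        assert view.columns["FLAG"].tolist() == [0x400, 0]

    def test_haplotypecaller_view_exposes_eight_fields(self):
        chunk = chunk100([10, 20])
        fd = FlagDelta(flags=np.array([0, 0]))
        qd = QualIndexDelta(qual=["J" * 100], index=np.array([1]))
        view = stage_view(chunk, "haplotypecaller", flag_delta=fd,
                          qual_index=qd)
        assert len(view.names()) == 8
        assert view.names() == ("RNAME", "POS", "MAPQ", "CIGAR", "SEQ",
                                "FLAG", "QUAL", "INDEX")
        assert view.columns["INDEX"].tolist() == [1]
        assert view.columns["QUAL"] == ["J" * 100]

    def test_missing_required_delta_names_namespace(self):
        with pytest.raises(ColsamError, match="flagdelta"):
            stage_view(chunk100([1]), "bqsr")
        with pytest.raises(ColsamError, match="qualindex"):
            stage_view(chunk100([1]), "haplotypecaller",
                       flag_delta=FlagDelta(flags=np.array([0])))


class TestFilterByIntervals:
    BED = IntervalSet.from_raw([("chr1", 100, 200)])

    def test_overlapping_read_survives(self):
        # pos=150 span 150..249 (1-based) overlaps interval 101..200
        idx = filter_by_intervals(chunk100([150]), self.BED)
        assert idx.tolist() == [0]

    def test_non_overlapping_read_filtered(self):
        idx = filter_by_intervals(chunk100([300]), self.BED)
        assert idx.tolist() == []

    def test_boundary_semantics_of_bed_half_open(self):
        # interval [100, 200) covers 1-based bases 101..200
        chunk = chunk100([1, 101, 201])  # spans 1..100, 101..200, 201..300
        idx = filter_by_intervals(chunk, self.BED)
        assert idx.tolist() == [1]

    def test_unaligned_rows_never_survive(self):
        rows = [{"pos": 0, "cigar": "*", "seq": "*", "qual": "*",
                 "rname": "chr1", "flag": 4}]
        chunk = Chunk(make_batch(rows), "chr1", sorted=True)
        assert filter_by_intervals(chunk, self.BED).tolist() == []

    def test_empty_interval_set_filters_everything(self):
        idx = filter_by_intervals(chunk100([150]), IntervalSet.from_raw([]))
        assert idx.tolist() == []


class TestApplyQualTransform:
    def test_identity_transform_copies_qualities(self):
        chunk = chunk100([10, 20, 30])
        delta = apply_qual_transform(chunk, np.array([0, 2]), lambda q: q)
        assert delta.qual == ["I" * 100, "I" * 100]
        assert delta.index.tolist() == [0, 2]

    def test_constant_transform_to_phred_30(self):
        chunk = chunk100([10])
        delta = apply_qual_transform(chunk, np.array([0]), lambda q: 30)
        assert delta.qual == ["?" * 100]   # 30 + 33 = 63 = '?'

    def test_empty_index_gives_empty_delta(self):
        delta = apply_qual_transform(chunk100([10]), np.array([], dtype=int),
                                     lambda q: q)
        assert len(delta) == 0

    def test_out_of_range_output_errors_only_when_hit(self):
        chunk = chunk100([10])  # all qualities are Phred 40
        delta = apply_qual_transform(chunk, np.array([0]), lambda q: q + 50)
        assert delta.qual == [chr(33 + 90) * 100]

    def test_out_of_range_output_reported_with_value(self):
        chunk = chunk100([10])
        with pytest.raises(ColsamError, match="outside 0..93"):
            apply_qual_transform(chunk, np.array([0]), lambda q: q + 60)


class TestResolveReads:
    def test_identity_deltas_give_source_with_updated_flags(self):
        chunk = chunk100([10, 20])
        fd = FlagDelta(flags=np.array([0x400, 0]))
        out = resolve_reads(chunk, fd)
        assert out.ints("flag").tolist() == [0x400, 0]
        assert out.strings("qual") == chunk.batch.strings("qual")

    def test_empty_index_gives_empty_batch(self):
        chunk = chunk100([10])
        qd = QualIndexDelta(qual=[], index=np.array([], dtype=int))
        assert resolve_reads(chunk, None, qd).num_rows == 0

    def test_equals_slice_with_substitution_column_by_column(self, sim_small):
        """resolve == slice_rows(source, index) with FLAG/QUAL swapped in."""
        parts = partition_by_chrom(sim_small.header, sim_small.batch)
        part = sort_partition(Partition("chr1", [Chunk(parts["chr1"], "chr1")]))
        chunk = part.chunks[0]
        intervals = IntervalSet.from_raw(
            [("chr1", s, s + 3000) for s in range(0, 150_000, 9000)])
        index = filter_by_intervals(chunk, intervals)
        assert 0 < len(index) < chunk.num_rows
        qd = apply_qual_transform(chunk, index, lambda q: min(q + 1, 93))
        flags = chunk.batch.ints("flag") ^ 0  # identity flag delta
        fd = FlagDelta(flags=flags)
        got = resolve_reads(chunk, fd, qd)
        expected = slice_rows(chunk.batch, index)
        for name in ("qname", "rname", "cigar", "rnext", "seq", "tags"):
            assert got.strings(name) == expected.strings(name)
        for name in ("pos", "mapq", "pnext", "tlen", "flag"):
            assert got.ints(name).tolist() == expected.ints(name).tolist()
        assert got.strings("qual") == qd.qual

    def test_resolution_preserves_coordinate_order(self):
        chunk = chunk100([10, 20, 30, 40])
        qd = QualIndexDelta(qual=["I" * 100] * 2, index=np.array([1, 3]))
        out = resolve_reads(chunk, None, qd)
        pos = out.ints("pos")
        assert np.all(np.diff(pos) >= 0)

    def test_inconsistent_delta_lengths_rejected(self):
        chunk = chunk100([10, 20])
        with pytest.raises(ColsamError, match="length"):
            resolve_reads(chunk, FlagDelta(flags=np.array([0])))


class TestExport:
    def _prepared_store(self, tmp_path, sim):
        store = ObjectStore(tmp_path / "store")
        store.set_header(sim.header)
        for chrom, batch in partition_by_chrom(sim.header, sim.batch).items():
            store.put(ObjectKey("aligned", chrom, 0), Chunk(batch, chrom))
        sort_all(store)
        return store

    def test_export_orders_by_header_then_position(self, tmp_path, sim_small):
        store = self._prepared_store(tmp_path, sim_small)
        buf = io.StringIO()
        n = export_final(store, sim_small.header, buf)
        assert n == sim_small.batch.num_rows
        _, batch = read_sam(io.StringIO(buf.getvalue()))
        rnames = batch.strings("rname")
        order = [c for i, c in enumerate(rnames) if c not in rnames[:i]]
        named = [c for c in order if c != "*"]
        assert named == [c for c in sim_small.header.references
                         if c in named]
        assert "*" not in rnames or order[-1] == "*"

    def test_per_chromosome_mode_writes_one_file_each(self, tmp_path,
                                                      sim_small):
        store = self._prepared_store(tmp_path, sim_small)
        outdir = tmp_path / "out"
        export_final(store, sim_small.header, outdir, per_chrom=True)
        names = sorted(p.name for p in outdir.iterdir())
        assert names == ["chr1.sam", "chr2.sam", "chr3.sam", "unmapped.sam"]

    def test_missing_namespace_errors(self, tmp_path):
        store = ObjectStore(tmp_path / "empty")
        with pytest.raises(ColsamError, match="sorted"):
            export_final(store, None, io.StringIO())
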