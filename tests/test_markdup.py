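"""Duplicate marking: geometry, scoring, truth tables, oracle equivalence."""

import re

import numpy as np
import pytest

from colsam.markdup import (
    duplicate_score,
    mark_duplicates_all,
    mark_duplicates_chunk,
    unclipped_5p,
)
from colsam.model import Chunk, ColsamError, Partition
from colsam.partition import partition_by_chrom
from colsam.sort import sort_all, sort_partition
from colsam.store import ObjectKey, ObjectStore

from conftest import make_batch, sorted_chunk


class TestUnclipped5p:
    @pytest.mark.parametrize("pos, cigar, strand, expected", [
        (100, "5S95M", "F", 95),
        (100, "95M5S", "R", 199),
        (100, "100M", "F", 100),
        (100, "100M", "R", 199),
        (100, "3H2S95M", "F", 95),
        (50, "40M10S", "R", 99),
        (50, "10S40M", "R", 89),
    ])
    def test_clip_corrected_ends(self, pos, cigar, strand, expected):
        assert unclipped_5p(pos, cigar, strand) == expected

    def test_star_cigar_rejected(self):
        with pytest.raises(ColsamError):
            unclipped_5p(100, "*", "F")


class TestDuplicateScore:
    def test_sum_of_base_qualities(self):
        assert duplicate_score("ACGT", "IIII", "sum_of_base_qualities") == 160

    def test_low_qualities_do_not_count(self):
        # '#' is Phred 2, below the quality-15 floor
        assert duplicate_score("ACGT", "####", "sum_of_base_qualities") == 0

    def test_total_mapped_length_counts_aligned_bases(self):
        score = duplicate_score("A" * 60, "I" * 60, "total_mapped_length",
                                cigar="50M10S")
        assert score == 50

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ColsamError, match="strategy"):
            duplicate_score("A", "I", "best_guess")


def read(qname, pos, cigar="100M", flag=0, qual_phred=30, rname="chr1",
         rnext="*", pnext=0, tags=""):
    length = sum(int(n) for n, op in
                 re.findall(r"(\d+)([MIS=X])", cigar))
    return {"qname": qname, "flag": flag, "rname": rname, "pos": pos,
            "cigar": cigar, "rnext": rnext, "pnext": pnext,
            "seq": "A" * length, "qual": chr(33 + qual_phred) * length,
            "tags": tags}


class TestMarkChunk:
    def test_lower_quality_copy_is_marked(self):
        chunk = sorted_chunk([read("hi", 100, qual_phred=40),
                              read("lo", 100, qual_phred=20)])
        delta = mark_duplicates_chunk(chunk)
        assert delta.flags.tolist() == [0, 0x400]

    def test_opposite_strands_are_distinct_groups(self):
        chunk = sorted_chunk([read("f", 100),
                              read("r", 100, flag=0x10)])
        delta = mark_duplicates_chunk(chunk)
        assert delta.flags.tolist() == [0, 0x10]

    def test_single_read_keeps_source_flags(self):
        chunk = sorted_chunk([read("only", 100)])
        assert mark_duplicates_chunk(chunk).flags.tolist() == [0]

    def test_clipped_copy_shares_unclipped_end(self):
        # 5S95M at 105 has the same unclipped 5' end as 100M at 100
        chunk = sorted_chunk([read("full", 100, "100M", qual_phred=40),
                              read("clip", 105, "5S95M", qual_phred=20)])
        delta = mark_duplicates_chunk(chunk)
        assert delta.flags.tolist() == [0, 0x400]

    def test_secondary_supplementary_unmapped_never_considered(self):
        chunk = sorted_chunk([
            read("a", 100, qual_phred=40),
            read("sec", 100, flag=0x100),
            read("sup", 100, flag=0x800),
            read("b", 100, qual_phred=20),
        ])
        delta = mark_duplicates_chunk(chunk)
        assert delta.flags.tolist() == [0, 0x100, 0x800, 0x400]

    def test_fragment_at_pair_end_is_marked_regardless_of_score(self):
        pair1 = read("p", 100, flag=0x1 | 0x20 | 0x40, rnext="=",
                     pnext=300, tags="MC:Z:100M")
        frag = read("f", 100, qual_phred=41)
        chunk = sorted_chunk([pair1, frag])
        delta = mark_duplicates_chunk(chunk)
        assert delta.flags.tolist() == [0x1 | 0x20 | 0x40, 0x400]

    def test_score_tie_breaks_by_qname(self):
        chunk = sorted_chunk([read("b", 100, qual_phred=30),
                              read("a", 100, qual_phred=30)])
        delta = mark_duplicates_chunk(chunk)
        # equal scores: lexicographically smaller qname survives
        assert delta.flags.tolist() == [0x400, 0]

    def test_unsorted_chunk_rejected(self):
        chunk = Chunk(make_batch([read("x", 5)]), "chr1", sorted=False)
        with pytest.raises(ColsamError, match="sorted"):
            mark_duplicates_chunk(chunk)

    def test_flag_delta_differs_only_in_duplicate_bit(self, sim_small):
        parts = partition_by_chrom(sim_small.header, sim_small.batch)
        for chrom in ("chr1", "chr2", "chr3"):
            part = sort_partition(
                Partition(chrom, [Chunk(parts[chrom], chrom)]))
            delta = mark_duplicates_chunk(part.chunks[0])
            src = part.chunks[0].batch.ints("flag")
            assert np.all(np.isin(delta.flags ^ src, [0, 0x400]))


# ---------------------------------------------------------------------------
# Independent O(n^2)-style grouping oracle (deliberately separate code path:
# its own CIGAR parsing, union-find grouping over all pairs of reads).
# ---------------------------------------------------------------------------

_ORACLE_CIG = re.compile(r"(\d+)([A-Z=])")


def _oracle_end(pos, cigar, reverse):
    ops = [(int(n), o) for n, o in _ORACLE_CIG.findall(cigar)]
    if not reverse:
        clip = 0
        for n, o in ops:
            if o in "SH":
                clip += n
            else:
                break
        return pos - clip
    ref = sum(n for n, o in ops if o in "MDN=X")
    clip = 0
    for n, o in reversed(ops):
        if o in "SH":
            clip += n
        else:
            break
    return pos + ref - 1 + clip


def _oracle_mark(rows, scoring="sum_of_base_qualities"):
    """All-pairs duplicate grouping; returns the set of marked qnames."""
    cands = []
    for r in rows:
        f = r["flag"]
        if f & (0x4 | 0x100 | 0x800) or r["cigar"] == "*" or r["pos"] < 1:
            continue
        end = (r["rname"], _oracle_end(r["pos"], r["cigar"], bool(f & 0x10)),
               "R" if f & 0x10 else "F")
        if scoring == "sum_of_base_qualities":
            score = sum(ord(c) - 33 for c in r["qual"] if ord(c) - 33 >= 15)
        else:
            score = sum(int(n) for n, o in _ORACLE_CIG.findall(r["cigar"])
                        if o in "M=X")
        paired = bool(f & 0x1) and not (f & 0x8)
        mate_end = None
        if paired:
            mchrom = r["rname"] if r["rnext"] == "=" else r["rnext"]
            mrev = bool(f & 0x20)
            mc = None
            for t in r["tags"].split("\t"):
                if t.startswith("MC:Z:"):
                    mc = t[5:]
            if mc:
                mate_end = (mchrom, _oracle_end(r["pnext"], mc, mrev),
                            "R" if mrev else "F")
            else:
                mate_end = (mchrom, r["pnext"], "R" if mrev else "F")
        cands.append(dict(qname=r["qname"], end=end, mate_end=mate_end,
                          score=score, paired=paired))

    marked = set()
    pair_ends = {c["end"] for c in cands if c["paired"]}
    # pair units keyed by canonical (end, mate_end); brute force over pairs
    units = {}
    for c in cands:
        if not c["paired"]:
            continue
        key = tuple(sorted([c["end"], c["mate_end"]]))
        u = units.setdefault(key, {}).setdefault(c["qname"],
                                                 {"score": 0, "qname": c["qname"]})
        u["score"] += c["score"]
    for key, group in units.items():
        if len(group) < 2:
            continue
        ranked = sorted(group.values(),
                        key=lambda u: (-u["score"], u["qname"]))
        marked |= {u["qname"] for u in ranked[1:]}
    # fragments: all-pairs comparison on ends
    frags = [c for c in cands if not c["paired"]]
    for i, a in enumerate(frags):
        if a["end"] in pair_ends:
            marked.add(a["qname"])
            continue
        beaten = False
        for j, b in enumerate(frags):
            if i == j or a["end"] != b["end"]:
                continue
            if (b["score"], a["qname"]) > (a["score"], b["qname"]):
                beaten = True
        if beaten:
            marked.add(a["qname"])
    return marked


def _marked_qnames(store):
    out = set()
    for key in store.list_keys("flagdelta"):
        delta = store.get(key)
        chunk = store.get(ObjectKey("sorted", key.chrom, key.ordinal))
        for q, f in zip(chunk.batch.strings("qname"), delta.flags):
            if f & 0x400:
                out.add(q)
    return out


def _run_markdup(tmp_path, sim, name, workers=1, max_bytes=None, pad_bp=600):
    store = ObjectStore(tmp_path / name)
    store.set_header(sim.header)
    for chrom, batch in partition_by_chrom(sim.header, sim.batch).items():
        store.put(ObjectKey("aligned", chrom, 0), Chunk(batch, chrom))
    sort_all(store, workers=workers, max_bytes=max_bytes, pad_bp=pad_bp)
    mark_duplicates_all(store, workers=workers)
    return store


class TestMarkAll:
    def test_marked_set_equals_simulator_truth(self, tmp_path, sim_small):
        store = _run_markdup(tmp_path, sim_small, "truth")
        truth = set(sim_small.truth[
            sim_small.truth.is_duplicate_expected].qname)
        assert _marked_qnames(store) == truth

    def test_exactly_g_minus_1_marks_per_group(self, tmp_path, sim_small):
        store = _run_markdup(tmp_path, sim_small, "gm1")
        marked = _marked_qnames(store)
        groups = sim_small.truth[sim_small.truth.group_id >= 0]
        for gid, members in groups.groupby("group_id"):
            names = set(members.qname)
            assert len(names & marked) == len(names) - 1

    def test_agrees_with_all_pairs_oracle(self, sim_small):
        """Chunk output equals an independent brute-force grouping."""
        parts = partition_by_chrom(sim_small.header, sim_small.batch)
        for chrom in ("chr1", "chr2", "chr3"):
            part = sort_partition(
                Partition(chrom, [Chunk(parts[chrom], chrom)]))
            chunk = part.chunks[0]
            delta = mark_duplicates_chunk(chunk)
            got = {q for q, f in zip(chunk.batch.strings("qname"),
                                     delta.flags) if f & 0x400}
            rows = [chunk.batch.row(i) for i in range(chunk.num_rows)]
            # oracle marks qnames; expected per-chrom marked qname set
            assert got == {q for q in _oracle_mark(rows)}

    def test_worker_count_does_not_change_deltas(self, tmp_path, sim_small):
        s1 = _run_markdup(tmp_path, sim_small, "w1", workers=1)
        s8 = _run_markdup(tmp_path, sim_small, "w8", workers=8)
        k1 = s1.list_keys("flagdelta")
        assert [k.name for k in k1] == [k.name for k in s8.list_keys("flagdelta")]
        for k in k1:
            assert s1.get(k).flags.tolist() == s8.get(k).flags.tolist()

    def test_chunked_equals_unchunked(self, tmp_path, sim_small):
        """Tiny chunks with sufficient padding reproduce the whole-
        chromosome result exactly."""
        whole = _run_markdup(tmp_path, sim_small, "whole", max_bytes=None)
        tiny = _run_markdup(tmp_path, sim_small, "tiny", max_bytes=1024,
                            pad_bp=600)
        assert len(tiny.list_keys("sorted")) > len(whole.list_keys("sorted"))
        assert _marked_qnames(tiny) == _marked_qnames(whole)

    def test_missing_sorted_namespace_errors(self, tmp_path):
        store = ObjectStore(tmp_path / "empty")
        with pytest.raises(ColsamError, match="sorted"):
            mark_duplicates_all(store)
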