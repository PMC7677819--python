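"""Synthetic SAM generator with known duplicate-group truth.

Emits aligner-style SAM (paired and single-end reads, soft clipping,
cross-chromosome mates, unmapped reads, shuffled record order) over a
configurable reference dictionary, together with a machine-readable
truth table that says exactly which reads a correct duplicate-marking
run must flag.  Every pipeline stage is therefore testable without any
external dataset.

Planted duplicate groups share unclipped 5′ end(s) and strand(s) *by
construction* — members differ in leading/trailing soft clip so the
clip-corrected geometry is genuinely exercised — and each member gets a
distinct constant per-base quality with one boosted winner, so the
expected survivor is unambiguous and truth tables do not depend on tie
breaking.  All other reads are given unclipped ends unique within their
(chromosome, strand), so no accidental duplicate groups arise.

Mapped mates stay within ``max_insert`` of each other; together with
chunk padding of at least ``max_insert + read_length + max_clip`` base
pairs this keeps duplicate decisions identical across any chunking of
the data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model import ColsamError, ReadBatch, SamHeader
from .samio import write_sam

__all__ = ["SimSpec", "SimResult", "simulate", "HUMAN_REFERENCES"]

#: A small human-style reference dictionary: 22 autosomes + X, Y, M.
HUMAN_REFERENCES: tuple[tuple[str, int], ...] = tuple(
    [(f"chr{i}", 150_000) for i in range(1, 23)]
    + [("chrX", 150_000), ("chrY", 80_000), ("chrM", 20_000)]
)

_PHRED_WINNER = 41  # boosted constant quality of each group's survivor


@dataclass(frozen=True)
class SimSpec:
    """Study conditions for one simulated sample."""

    references: tuple[tuple[str, int], ...] = HUMAN_REFERENCES
    n_fragments: int = 3000          #: non-duplicate fragments
    read_length: int = 100
    paired_fraction: float = 0.7
    duplicate_groups: int = 200
    group_size_min: int = 2
    group_size_max: int = 5
    softclip_prob: float = 0.3
    max_clip: int = 10
    cross_chrom_mate_prob: float = 0.01
    unmapped_fraction: float = 0.02
    qual_range: tuple[int, int] = (20, 40)
    max_insert: int = 300            #: outermost template span, bp
    seed: int = 0


@dataclass
class SimResult:
    header: SamHeader
    batch: ReadBatch
    truth: pd.DataFrame             #: columns qname, group_id, is_duplicate_expected

    def sam_text(self) -> str:
        buf = io.StringIO()
        write_sam(self.header, self.batch, buf)
        return buf.getvalue()

    def write(self, sam_path, truth_path=None) -> None:
        write_sam(self.header, self.batch, sam_path)
        if truth_path is not None:
            self.truth.to_csv(truth_path, sep="\t", index=False)


class _Sim:
    def __init__(self, spec: SimSpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self.rows: list[dict] = []
        self.truth: list[tuple[str, int, bool]] = []
        # per chromosome: set of used (strand, unclipped 5' end)
        self.used: dict[str, set] = {name: set() for name, _ in spec.references}
        self.ref_names = [name for name, _ in spec.references]
        self.ref_lengths = dict(spec.references)
        lengths = np.array([ln for _, ln in spec.references], dtype=float)
        self.ref_weights = lengths / lengths.sum()
        self._serial = 0

    # -- low level ---------------------------------------------------------
    def _qname(self, prefix: str) -> str:
        self._serial += 1
        return f"{prefix}{self._serial:06d}"

    def _seq(self) -> str:
        letters = np.frombuffer(b"ACGT", dtype="S1")
        return b"".join(
            letters[self.rng.integers(0, 4, self.spec.read_length)]
        ).decode("ascii")

    def _qual_random(self) -> str:
        lo, hi = self.spec.qual_range
        q = self.rng.integers(lo, hi + 1, self.spec.read_length)
        return "".join(chr(33 + int(v)) for v in q)

    def _qual_const(self, phred: int) -> str:
        return chr(33 + phred) * self.spec.read_length

    def _clip(self) -> int:
        if self.rng.random() < self.spec.softclip_prob:
            return int(self.rng.integers(1, self.spec.max_clip + 1))
        return 0

    def _pick_chrom(self) -> str:
        return self.ref_names[
            int(self.rng.choice(len(self.ref_names), p=self.ref_weights))]

    def _free_end(self, chrom: str, strand: str,
                  lo: int, hi: int) -> int:
        """Sample an unclipped 5' end unused on (chrom, strand)."""
        used = self.used[chrom]
        for _ in range(10_000):
            u = int(self.rng.integers(lo, hi + 1))
            if (strand, u) not in used:
                used.add((strand, u))
                return u
        raise ColsamError(
            f"could not find a free 5' end on {chrom} in [{lo}, {hi}]; "
            "reference too small for the requested read count")

    def _row(self, qname, flag, rname, pos, mapq, cigar, rnext, pnext,
             tlen, seq, qual, tags) -> None:
        self.rows.append(dict(qname=qname, flag=flag, rname=rname, pos=pos,
                              mapq=mapq, cigar=cigar, rnext=rnext,
                              pnext=pnext, tlen=tlen, seq=seq, qual=qual,
                              tags=tags))

    # -- read constructors -------------------------------------------------
    def _fwd_cigar(self, clip: int) -> str:
        L = self.spec.read_length
        return f"{clip}S{L - clip}M" if clip else f"{L}M"

    def _rev_cigar(self, clip: int) -> str:
        L = self.spec.read_length
        return f"{L - clip}M{clip}S" if clip else f"{L}M"

    def _pair_rows(self, qname: str, chrom1: str, u1: int, chrom2: str,
                   u2_end: int, clip1: int, clip2: int,
                   qual1: str, qual2: str, proper: bool) -> None:
        """Emit one F/R read pair.

        ``u1`` is the forward read's unclipped 5' end, ``u2_end`` the
        reverse read's unclipped 5' end (its rightmost unclipped
        position).
        """
        L = self.spec.read_length
        pos1 = u1 + clip1
        cigar1 = self._fwd_cigar(clip1)
        # reverse read: trailing clip; end = pos2 + (L-clip2) - 1 + clip2
        pos2 = u2_end - L + 1
        cigar2 = self._rev_cigar(clip2)
        same = chrom1 == chrom2
        flag1 = 0x1 | 0x20 | 0x40 | (0x2 if proper and same else 0)
        flag2 = 0x1 | 0x10 | 0x80 | (0x2 if proper and same else 0)
        if same:
            tlen1 = u2_end - pos1 + 1
            tlen = (tlen1, -tlen1)
            rnext = ("=", "=")
        else:
            tlen = (0, 0)
            rnext = (chrom2, chrom1)
        self._row(qname, flag1, chrom1, pos1, 60, cigar1, rnext[0], pos2,
                  tlen[0], self._seq(), qual1, f"MC:Z:{cigar2}")
        self._row(qname, flag2, chrom2, pos2, 60, cigar2, rnext[1], pos1,
                  tlen[1], self._seq(), qual2, f"MC:Z:{cigar1}")

    def _single_row(self, qname: str, chrom: str, u: int, strand: str,
                    clip: int, qual: str) -> None:
        L = self.spec.read_length
        if strand == "F":
            pos, cigar, flag = u + clip, self._fwd_cigar(clip), 0
        else:
            pos, cigar, flag = u - L + 1, self._rev_cigar(clip), 0x10
        self._row(qname, flag, chrom, pos, 60, cigar, "*", 0, 0,
                  self._seq(), qual, "")

    # -- fragment emission -------------------------------------------------
    def _emit_background_fragment(self) -> str:
        """One non-duplicate fragment; returns its qname."""
        spec = self.spec
        L = spec.read_length
        u = self.rng.random()
        if u < spec.unmapped_fraction:
            qname = self._qname("unm")
            self._row(qname, 0x4, "*", 0, 0, "*", "*", 0, 0,
                      self._seq(), self._qual_random(), "")
            return qname
        if u < spec.unmapped_fraction + spec.paired_fraction:
            qname = self._qname("pair")
            chrom1 = self._pick_chrom()
            clip1, clip2 = self._clip(), self._clip()
            if self.rng.random() < spec.cross_chrom_mate_prob:
                chrom2 = self._pick_chrom()
                while chrom2 == chrom1:
                    chrom2 = self._pick_chrom()
                u1 = self._free_end(chrom1, "F", spec.max_clip + 1,
                                    self.ref_lengths[chrom1] - L)
                u2 = self._free_end(chrom2, "R", L + spec.max_clip,
                                    self.ref_lengths[chrom2] - spec.max_clip)
                self._pair_rows(qname, chrom1, u1, chrom2, u2,
                                clip1, clip2, self._qual_random(),
                                self._qual_random(), proper=False)
            else:
                u1, u2 = self._paired_anchors(chrom1)
                self._pair_rows(qname, chrom1, u1, chrom1, u2,
                                clip1, clip2, self._qual_random(),
                                self._qual_random(), proper=True)
            return qname
        qname = self._qname("frag")
        chrom = self._pick_chrom()
        strand = "F" if self.rng.random() < 0.5 else "R"
        clip = self._clip()
        if strand == "F":
            u = self._free_end(chrom, "F", spec.max_clip + 1,
                               self.ref_lengths[chrom] - L)
        else:
            u = self._free_end(chrom, "R", L + spec.max_clip,
                               self.ref_lengths[chrom] - spec.max_clip)
        self._single_row(qname, chrom, u, strand, clip, self._qual_random())
        return qname

    def _paired_anchors(self, chrom: str) -> tuple[int, int]:
        """Unused (forward 5' end, reverse 5' end) anchors for one
        same-chromosome template."""
        spec = self.spec
        L = spec.read_length
        used = self.used[chrom]
        for _ in range(10_000):
            u1 = int(self.rng.integers(
                spec.max_clip + 1,
                self.ref_lengths[chrom] - spec.max_insert - spec.max_clip + 1))
            insert = int(self.rng.integers(L + 2 * spec.max_clip,
                                           spec.max_insert + 1))
            u2 = u1 + insert - 1
            if ("F", u1) not in used and ("R", u2) not in used:
                used.add(("F", u1))
                used.add(("R", u2))
                return u1, u2
        raise ColsamError(
            f"could not place a read pair on {chrom}; reference too small "
            "for the requested read count")

    def _emit_duplicate_group(self, gid: int) -> None:
        spec = self.spec
        L = spec.read_length
        size = int(self.rng.integers(spec.group_size_min,
                                     spec.group_size_max + 1))
        paired = self.rng.random() < spec.paired_fraction
        chrom = self._pick_chrom()
        if paired:
            u1, u2 = self._paired_anchors(chrom)
            for m in range(size):
                qname = f"grp{gid:04d}_m{m}"
                phred = _PHRED_WINNER if m == 0 else 16 + m
                self._pair_rows(qname, chrom, u1, chrom, u2,
                                self._clip(), self._clip(),
                                self._qual_const(phred),
                                self._qual_const(phred), proper=True)
                self.truth.append((qname, gid, m != 0))
        else:
            strand = "F" if self.rng.random() < 0.5 else "R"
            if strand == "F":
                u = self._free_end(chrom, "F", spec.max_clip + 1,
                                   self.ref_lengths[chrom] - L)
            else:
                u = self._free_end(chrom, "R", L + spec.max_clip,
                                   self.ref_lengths[chrom] - spec.max_clip)
            for m in range(size):
                qname = f"grp{gid:04d}_m{m}"
                phred = _PHRED_WINNER if m == 0 else 16 + m
                self._single_row(qname, chrom, u, strand, self._clip(),
                                 self._qual_const(phred))
                self.truth.append((qname, gid, m != 0))

    def run(self) -> SimResult:
        spec = self.spec
        min_len = min(ln for _, ln in spec.references)
        if spec.read_length + spec.max_insert + 2 * spec.max_clip >= min_len:
            raise ColsamError(
                f"read_length + max_insert too large for the smallest "
                f"reference ({min_len} bp)")
        if spec.max_insert < spec.read_length + 2 * spec.max_clip:
            raise ColsamError(
                "max_insert must be at least read_length + 2*max_clip "
                "to place a read pair")
        if not (spec.group_size_min >= 2
                and spec.group_size_max >= spec.group_size_min):
            raise ColsamError("duplicate group sizes must satisfy "
                              "2 <= min <= max")
        if spec.group_size_max > 1 + (_PHRED_WINNER - 17):
            raise ColsamError("group_size_max too large for distinct scores")
        for _ in range(spec.n_fragments):
            qname = self._emit_background_fragment()
            self.truth.append((qname, -1, False))
        for gid in range(spec.duplicate_groups):
            self._emit_duplicate_group(gid)

        order = self.rng.permutation(len(self.rows))
        rows = [self.rows[i] for i in order]
        cols = {name: [r[name] for r in rows]
                for name in ("qname", "flag", "rname", "pos", "mapq", "cigar",
                             "rnext", "pnext", "tlen", "seq", "qual", "tags")}
        batch = ReadBatch.from_pydict(cols)
        header_lines = ["@HD\tVN:1.6\tSO:unknown"] + [
            f"@SQ\tSN:{name}\tLN:{ln}" for name, ln in spec.references]
        header = SamHeader.parse(header_lines)
        truth = pd.DataFrame(self.truth, columns=[
            "qname", "group_id", "is_duplicate_expected"])
        truth = truth.sort_values("qname", kind="stable").reset_index(drop=True)
        return SimResult(header, batch, truth)


def simulate(spec: SimSpec | None = None, **overrides) -> SimResult:
    """Generate one synthetic sample under ``spec`` (keyword overrides
    accepted); deterministic under the spec's seed."""
    spec = spec or SimSpec()
    if overrides:
        spec = replace(spec, **overrides)
    return _Sim(spec).run()
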