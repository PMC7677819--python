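"""Shared fixtures: small synthetic samples and store helpers."""

import pytest

from colsam.model import Chunk, ReadBatch
from colsam.simulate import SimSpec, simulate

THREE_CHROMS = (("chr1", 150_000), ("chr2", 150_000), ("chr3", 80_000))


def make_batch(rows):
    """Build a ReadBatch from a list of per-row dicts with defaults."""
    defaults = dict(qname="r", flag=0, rname="chr1", pos=1, mapq=60,
                    cigar="4M", rnext="*", pnext=0, tlen=0, seq="ACGT",
                    qual="IIII", tags="")
    cols = {k: [] for k in defaults}
    for i, row in enumerate(rows):
        merged = {**defaults, "qname": f"r{i}", **row}
        for k in cols:
            cols[k].append(merged[k])
    return ReadBatch.from_pydict(cols)


def sorted_chunk(rows, chrom="chr1"):
    """A single sorted chunk over `rows` (must be given in pos order)."""
    return Chunk(make_batch(rows), chrom, 0, sorted=True)


@pytest.fixture(scope="session")
def sim_small():
    """~2k reads on three chromosomes with planted duplicate groups."""
    return simulate(SimSpec(references=THREE_CHROMS, n_fragments=1000,
                            duplicate_groups=50, seed=11))


@pytest.fixture(scope="session")
def sim_human():
    """~3.5k reads over the 25-reference human-style dictionary."""
    return simulate(SimSpec(n_fragments=2000, duplicate_groups=40, seed=12))
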