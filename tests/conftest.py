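from __future__ import annotations

import numpy as np
import pytest

from clipins.io_alignment import AlignedRead, ReferenceAccessor
from clipins.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A small diploid dataset: 120 kb, 8 insertions of 50-300 bp, 30X."""
    cfg = SimConfig(genome_len=120_000, n_insertions=8, size_range=(50, 300),
                    coverage=30.0, seed=3)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_ref(small_sim):
    return ReferenceAccessor({small_sim.contig: small_sim.reference})


def make_read(
    name="r1",
    pos=1000,
    cigar=((  "M", 150),),
    seq=None,
    contig="chr1",
    mate_pos=2000,
    tlen=0,
    mapped=True,
    mate_mapped=True,
    is_read1=True,
    mapq=60,
):
    cig = [tuple(c) for c in cigar]
    if seq is None:
        n = sum(l for op, l in cig if op in "MIS=X") or 150
        rng = np.random.default_rng(abs(hash(name)) % 2**31)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
    return AlignedRead(
        query_name=name,
        is_mapped=mapped,
        contig=contig,
        pos=pos,
        cigar=cig if mapped else [],
        seq=seq,
        mate_is_mapped=mate_mapped,
        mate_pos=mate_pos,
        template_len=tlen,
        mapq=mapq,
        is_read1=is_read1,
    )
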