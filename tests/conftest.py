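"""Shared fixtures: record builders and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")

from tescan import (
    AlignmentRecord,
    ConsensusLibrary,
    GermlineSpec,
    ReadPairRecord,
    SimulationConfig,
    SomaticFamilySpec,
    build_population,
    simulate_read_pairs,
)
from tescan.simulate import random_genome, synthetic_library


def make_read(
    qname="q1",
    read_index=1,
    mapped=True,
    chrom="chr1",
    pos=1000,
    strand="+",
    mapq=60,
    cigar=None,
    seq=None,
    length=100,
    mate_mapped=True,
    proper=True,
    tlen=450,
    secondary=False,
) -> AlignmentRecord:
    if cigar is None:
        cigar = [("M", length)] if mapped else []
    if seq is None:
        seq = "A" * length
    return AlignmentRecord(
        qname=qname,
        read_index=read_index,
        mapped=mapped,
        chrom=chrom if mapped else None,
        pos=pos if mapped else -1,
        strand=strand,
        mapq=mapq if mapped else 0,
        cigar=cigar,
        seq=seq,
        is_secondary=secondary,
        is_supplementary=False,
        mate_chrom=chrom if mate_mapped else None,
        mate_pos=pos,
        mate_mapped=mate_mapped,
        proper_flag=proper,
        tlen=tlen,
    )


def make_pair(r1=None, r2=None, **kw) -> ReadPairRecord:
    if r1 is None:
        r1 = make_read(read_index=1, **kw)
    if r2 is None:
        r2 = make_read(read_index=2, strand="-", **kw)
    return ReadPairRecord(r1, r2)


@pytest.fixture(scope="session")
def small_library() -> ConsensusLibrary:
    return synthetic_library(8, (1500, 3500), seed=42)


@pytest.fixture(scope="session")
def small_genome():
    return [random_genome(300_000, seed=43)]


@pytest.fixture(scope="session")
def small_simulation(small_genome, small_library):
    """A compact germline+somatic population and its reads, reused by
    several integration tests."""
    rng = np.random.default_rng(7)
    config = SimulationConfig(
        n_genomes=200,
        depth=20.0,
        germline=GermlineSpec(n_insertions=20, min_spacing=3000),
        somatic=[SomaticFamilySpec("TE001", 2)],
        chimera_rate=0.001,
    )
    pop = build_population(small_genome, small_library, config, rng)
    readset = simulate_read_pairs(pop, rng)
    return pop, readset
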