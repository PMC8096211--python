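from collections import Counter

import numpy as np
import pytest

from tescan import (
    GermlineSpec,
    SimulationConfig,
    SomaticFamilySpec,
    build_population,
    emit_truth,
    inject_chimeras,
    simulate_read_pairs,
)
from tescan.simulate import random_genome, synthetic_library


def _small_cfg(**kw):
    defaults = dict(
        n_genomes=1000,
        depth=10.0,
        germline=GermlineSpec(n_insertions=20, min_spacing=3000),
        somatic=[],
        chimera_rate=0.0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="module")
def genome():
    return [random_genome(300_000, seed=1)]


@pytest.fixture(scope="module")
def library():
    return synthetic_library(6, (1500, 3000), seed=2)


class TestBuildPopulation:
    def test_frequency_design_is_balanced(self, genome, library):
        pop = build_population(genome, library, _small_cfg(), seed=3)
        freqs = Counter(r.frequency for r in pop.germline)
        assert freqs == {0.25: 5, 0.5: 5, 0.75: 5, 1.0: 5}

    def test_partial_fraction(self, genome, library):
        cfg = _small_cfg(germline=GermlineSpec(n_insertions=40, min_spacing=3000))
        pop = build_population(genome, library, cfg, seed=3)
        n_partial = sum(
            1
            for r in pop.germline
            if r.te_start > 0 or r.te_end < len(library.entries[r.transposon])
        )
        assert n_partial == 4  # 10% of 40

    def test_min_spacing_respected(self, genome, library):
        pop = build_population(genome, library, _small_cfg(), seed=3)
        pos = sorted(r.pos for r in pop.germline)
        assert min(b - a for a, b in zip(pos, pos[1:])) >= 3000

    def test_somatic_events_one_per_genome_slot(self, genome, library):
        cfg = _small_cfg(germline=None, somatic=[SomaticFamilySpec("TE001", 2)])
        pop = build_population(genome, library, cfg, seed=3)
        assert len(pop.somatic) == 2 * 1000
        assert pop.somatic_counts_per_genome()["TE001"] == 2
        assert all(r.frequency == 1 / 1000 for r in pop.somatic)

    def test_genome_too_small_errors(self, library):
        tiny = [random_genome(20_000, seed=9)]
        with pytest.raises(ValueError):
            build_population(tiny, library, _small_cfg(), seed=3)

    def test_deterministic_truth_under_fixed_seed(self, genome, library):
        a = build_population(genome, library, _small_cfg(), seed=11)
        b = build_population(genome, library, _small_cfg(), seed=11)
        assert a.germline == b.germline


class TestSimulateReads:
    def test_read_count_matches_depth_within_poisson(self, genome, library):
        cfg = _small_cfg()
        pop = build_population(genome, library, cfg, seed=5)
        rs = simulate_read_pairs(pop, seed=5)
        expected = cfg.depth * 300_000 / 200
        assert abs(rs.n_pairs - expected) < 4 * np.sqrt(expected)

    def test_zero_error_rate_reads_are_exact_substrings(self, genome, library):
        from tescan.simulate import ReadSimParams, _revcomp

        cfg = _small_cfg()
        cfg.read = ReadSimParams(error_rate=0.0)
        pop = build_population(genome, library, cfg, seed=6)
        rs = simulate_read_pairs(pop, seed=6)
        haystacks = [genome[0].sequence] + [
            library.entries[r.transposon] for r in pop.germline
        ]
        joined = "\n".join(haystacks)
        joined_rc = _revcomp(joined)
        checked = 0
        for pair in rs.featured[:50]:
            for read in pair.reads:
                if read.seq is None or len(read.seq) < 100:
                    continue
                # junction reads are splices of genome and consensus; each
                # mapped/clipped segment must be an exact substring
                if read.mapped and read.cigar == [("M", 100)]:
                    assert read.seq in joined or read.seq in joined_rc
                    checked += 1
        assert checked > 5

    def test_bitwise_reproducible(self, genome, library):
        cfg = _small_cfg(chimera_rate=0.001)
        pop1 = build_population(genome, library, cfg, seed=8)
        rs1 = simulate_read_pairs(pop1, seed=9)
        pop2 = build_population(genome, library, cfg, seed=8)
        rs2 = simulate_read_pairs(pop2, seed=9)
        assert rs1.n_pairs == rs2.n_pairs
        assert np.array_equal(rs1.bulk.start1, rs2.bulk.start1)
        sig1 = [(p.r1.qname, p.r1.pos, p.r1.seq, p.r2.seq) for p in rs1.featured]
        sig2 = [(p.r1.qname, p.r1.pos, p.r1.seq, p.r2.seq) for p in rs2.featured]
        assert sig1 == sig2

    def test_junction_fragments_scale_with_depth_and_frequency(self, genome, library):
        # supporting evidence per insertion grows linearly in depth x freq
        from tescan import call_insertions

        counts = {}
        for depth in (5.0, 20.0):
            cfg = _small_cfg(depth=depth)
            pop = build_population(genome, library, cfg, seed=12)
            rs = simulate_read_pairs(pop, seed=13)
            res = call_insertions(rs, library)
            for rec in pop.germline:
                match = [
                    c for c in res.calls if abs(c.breakpoint - rec.pos) <= 50
                ]
                if match:
                    counts.setdefault(depth, []).append(
                        (rec.frequency, match[0].n_support)
                    )
        for depth, rows in counts.items():
            per_unit = [s / (f * depth) for f, s in rows]
            slope = np.mean(per_unit)
            assert slope == pytest.approx(4.2, rel=0.25)


class TestChimeras:
    def test_expected_chimera_count(self, genome, library):
        cfg = _small_cfg(chimera_rate=0.005)
        pop = build_population(genome, library, cfg, seed=20)
        rs = simulate_read_pairs(pop, seed=20)
        n_chim = sum(p.is_chimera_truth for p in rs.featured) + sum(
            p.is_chimera_truth for p in rs.iter_unanchored()
        )
        expected = 0.005 * rs.n_pairs
        assert abs(n_chim - expected) < 5 * np.sqrt(expected)

    def test_rate_zero_identity(self):
        from conftest import make_pair

        pairs = [make_pair(qname=f"q{i}") for i in range(100)]
        out, n = inject_chimeras(pairs, 0.0, seed=1)
        assert n == 0 and out == pairs

    def test_flag_count_equals_replacement_count(self):
        from conftest import make_pair

        pairs = [make_pair(qname=f"q{i}", pos=1000 + 500 * i) for i in range(2000)]
        out, n = inject_chimeras(pairs, 0.01, seed=2)
        assert len(out) == len(pairs)
        assert sum(p.is_chimera_truth for p in out) == n
        assert n > 0

    def test_chimeras_never_proper(self):
        from conftest import make_pair

        pairs = [make_pair(qname=f"q{i}", pos=1000 + 500 * i) for i in range(500)]
        out, _ = inject_chimeras(pairs, 0.05, seed=3)
        for p in out:
            if p.is_chimera_truth:
                assert not (p.r1.proper_flag or p.r2.proper_flag)


class TestTruthOutputs:
    def test_truth_files(self, tmp_path, genome, library):
        cfg = _small_cfg(somatic=[SomaticFamilySpec("TE001", 2),
                                  SomaticFamilySpec("TE002", 1)])
        pop = build_population(genome, library, cfg, seed=30)
        paths = emit_truth(pop, tmp_path)
        bed_lines = paths["germline_bed"].read_text().splitlines()
        assert len(bed_lines) == 20
        tsv = paths["somatic_tsv"].read_text().splitlines()
        rows = dict(line.split("\t")[:2] for line in tsv[1:])
        assert rows["TE001"] == "2.0"
        assert rows["TE003"] == "0.0"

    def test_empty_somatic_config(self, tmp_path, genome, library):
        pop = build_population(genome, library, _small_cfg(), seed=31)
        paths = emit_truth(pop, tmp_path)
        tsv = paths["somatic_tsv"].read_text().splitlines()
        assert all(line.split("\t")[1] == "0.0" for line in tsv[1:])
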