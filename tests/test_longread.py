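import numpy as np
import pysam
import pytest

from tescan import (
    ConsensusLibrary,
    extract_long_insertions,
    longread_frequency,
    merge_and_filter,
    validate_te_insertion,
)
from tescan.longread import CuratedInsertion, LongReadInsertionEvent
from tescan.simulate import _random_dna, _revcomp, random_genome

HEADER = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 200_000}]}


def make_segment(qname, pos, cigar, seq):
    a = pysam.AlignedSegment(pysam.AlignmentHeader.from_dict(HEADER))
    a.query_name = qname
    a.reference_id = 0
    a.reference_start = pos
    a.mapping_quality = 60
    a.cigarstring = cigar
    a.query_sequence = seq
    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
    return a


@pytest.fixture(scope="module")
def library():
    rng = np.random.default_rng(77)
    return ConsensusLibrary({"TE_A": _random_dna(rng, 4000), "TE_B": _random_dna(rng, 2000)})


@pytest.fixture(scope="module")
def genome():
    return random_genome(200_000, seed=78)


class TestExtract:
    def test_cigar_arithmetic(self, genome):
        seq = genome.sequence[5000:6000] + "A" * 400 + genome.sequence[6000:7000]
        rec = make_segment("r1", 5000, "1000M400I1000M", seq)
        (ev,) = extract_long_insertions([rec])
        assert ev.position == 6000
        assert ev.length == 400
        assert ev.sequence == "A" * 400

    def test_short_insertion_excluded(self, genome):
        seq = genome.sequence[5000:6000] + "A" * 250 + genome.sequence[6000:7000]
        rec = make_segment("r1", 5000, "1000M250I1000M", seq)
        assert extract_long_insertions([rec]) == []

    def test_two_insertions_two_events(self, genome):
        seq = (
            genome.sequence[5000:5600] + "A" * 300
            + genome.sequence[5600:6200] + "C" * 300
            + genome.sequence[6200:6800]
        )
        rec = make_segment("r1", 5000, "600M300I600M300I600M", seq)
        events = extract_long_insertions([rec])
        assert [e.position for e in events] == [5600, 6200]


class TestValidate:
    def test_full_insert_valid(self, library):
        ev = LongReadInsertionEvent("chr1", 6000, library.entries["TE_A"], "r1")
        assert validate_te_insertion(ev, library) == "TE_A"
        assert ev.te_start == 0 and ev.te_end == 4000

    def test_alignment_covering_half_or_less_invalid(self, library):
        rng = np.random.default_rng(1)
        # 4000-nt insert of which only 1900 nt are transposon
        seq = library.entries["TE_A"][:1900] + _random_dna(rng, 2100)
        ev = LongReadInsertionEvent("chr1", 6000, seq, "r1")
        assert validate_te_insertion(ev, library) is None

    def test_alignment_far_from_insert_end_invalid(self, library):
        rng = np.random.default_rng(2)
        # TE match starts 600 nt into the insert: outside the 500-nt window
        seq = _random_dna(rng, 600) + library.entries["TE_A"][:3000]
        ev = LongReadInsertionEvent("chr1", 6000, seq, "r1")
        assert validate_te_insertion(ev, library) is None

    def test_reverse_orientation_insert_valid(self, library):
        ev = LongReadInsertionEvent(
            "chr1", 6000, _revcomp(library.entries["TE_B"]), "r1"
        )
        assert validate_te_insertion(ev, library) == "TE_B"


class TestMergeAndFilter:
    def _event(self, pos, read, te="TE_A"):
        ev = LongReadInsertionEvent("chr1", pos, "A" * 400, read)
        ev.transposon, ev.te_start, ev.te_end = te, 0, 400
        return ev

    def test_mode_breakpoint_and_merge(self):
        events = [self._event(10_000, f"r{i}") for i in range(3)] + [
            self._event(10_020, "r3")
        ]
        (ins,) = merge_and_filter(events)
        assert ins.breakpoint == 10_000
        assert ins.n_supporting == 4

    def test_lone_event_dropped(self):
        assert merge_and_filter([self._event(10_000, "r1")]) == []

    def test_events_beyond_merge_distance_stay_separate(self):
        events = (
            [self._event(10_000, f"a{i}") for i in range(2)]
            + [self._event(10_060, f"b{i}") for i in range(2)]
        )
        merged = merge_and_filter(events)
        assert [m.breakpoint for m in merged] == [10_000, 10_060]

    def test_no_curated_insertion_below_two_reads(self):
        events = [self._event(10_000, "r1"), self._event(10_000, "r1")]
        # same read twice is still one supporting read
        assert merge_and_filter(events) == []


class TestFrequency:
    def _reference_read(self, qname, genome, start, end):
        return make_segment(
            qname, start, f"{end - start}M", genome.sequence[start:end]
        )

    def _insertion_read(self, qname, genome, bp, flank, insert):
        seq = genome.sequence[bp - flank : bp] + insert + genome.sequence[bp : bp + flank]
        return make_segment(qname, bp - flank, f"{flank}M{len(insert)}I{flank}M", seq)

    def test_double_counted_split_reads(self, genome):
        bp = 50_000
        insert = "A" * 400
        records = (
            [self._insertion_read(f"s{i}", genome, bp, 800, insert) for i in range(2)]
            + [self._reference_read(f"r{i}", genome, bp - 700, bp + 700) for i in range(4)]
        )
        ins = CuratedInsertion("chr1", bp, "TE_A", 2)
        freq = longread_frequency(ins, records)
        # two I-op reads count twice each: S=4, R=4 -> 4/12
        assert freq == pytest.approx(4 / 12)

    def test_no_reference_reads_gives_one(self, genome):
        bp = 50_000
        records = [self._insertion_read("s0", genome, bp, 800, "A" * 400)]
        ins = CuratedInsertion("chr1", bp, "TE_A", 1)
        assert longread_frequency(ins, records) == 1.0

    def test_shallow_crossing_not_reference(self, genome):
        bp = 50_000
        records = [
            self._insertion_read("s0", genome, bp, 800, "A" * 400),
            self._reference_read("r0", genome, bp - 700, bp + 30),  # 30 < 50
        ]
        ins = CuratedInsertion("chr1", bp, "TE_A", 1)
        assert longread_frequency(ins, records) == 1.0

    def test_half_frequency_population_within_binomial_ci(self, genome, library):
        """A 50/50 carrier population: estimated frequency must fall in the
        95% binomial interval of p=0.5."""
        rng = np.random.default_rng(55)
        bp = 100_000
        insert = library.entries["TE_B"]
        records = []
        n_reads = 60
        carriers = 0
        for i in range(n_reads):
            if rng.random() < 0.5:
                carriers += 1
                records.append(self._insertion_read(f"c{i}", genome, bp, 1000, insert))
            else:
                records.append(self._reference_read(f"n{i}", genome, bp - 1000, bp + 1000))
        ins = CuratedInsertion("chr1", bp, "TE_B", carriers)
        freq = longread_frequency(ins, records)
        # S = 2*carriers, R = n - carriers: p_hat = S/(S+2R) = carriers/n
        assert freq == pytest.approx(carriers / n_reads, abs=1e-9)
        sd = np.sqrt(0.25 / n_reads)
        assert abs(freq - 0.5) < 3 * sd

    def test_shared_estimator_with_short_read_module(self):
        from tescan import estimate_insertion_frequency

        assert estimate_insertion_frequency(4, 4) == pytest.approx(4 / 12)


class TestEndToEndCuration:
    def test_curate_from_sam(self, tmp_path, genome, library):
        from tescan import curate_benchmark

        bp1, bp2 = 40_000, 120_000
        path = tmp_path / "lr.sam"
        with pysam.AlignmentFile(
            path, "wh", header=pysam.AlignmentHeader.from_dict(HEADER)
        ) as out:
            for i in range(3):
                seq = (
                    genome.sequence[bp1 - 2000 : bp1]
                    + library.entries["TE_A"]
                    + genome.sequence[bp1 : bp1 + 2000]
                )
                out.write(make_segment(f"a{i}", bp1 - 2000, "2000M4000I2000M", seq))
            # single-read insertion: must be dropped
            seq = (
                genome.sequence[bp2 - 2000 : bp2]
                + library.entries["TE_B"]
                + genome.sequence[bp2 : bp2 + 2000]
            )
            out.write(make_segment("b0", bp2 - 2000, "2000M2000I2000M", seq))
            for i in range(3):
                out.write(
                    make_segment(
                        f"ref{i}", bp1 - 1500,
                        "3000M", genome.sequence[bp1 - 1500 : bp1 + 1500],
                    )
                )
        curated = curate_benchmark(str(path), library)
        assert len(curated) == 1
        ins = curated[0]
        assert (ins.chrom, ins.breakpoint, ins.transposon) == ("chr1", bp1, "TE_A")
        assert ins.n_supporting == 3
        # S = 3 I-op reads x2 = 6, R = 3 -> 6/12
        assert ins.frequency == pytest.approx(0.5)
        assert (ins.te_start, ins.te_end) == (0, 4000)
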