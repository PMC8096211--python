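import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tescan import (
    call_breakpoint,
    classify_cluster,
    cluster_supporting_reads,
    estimate_insertion_frequency,
    predict_te_ends,
)
from tescan.consensus import ConsensusHit, SupportingRead

F95 = 466.0


def make_hit(te="TE_A", start=0, end=100, strand="-", family=None):
    return ConsensusHit(
        transposon=te, family=family or te, hit_start=start, hit_end=end,
        strand=strand, aligned_length=end - start, identity=1.0,
        score=float(end - start), q_start=0, q_end=end - start,
    )


def make_sr(pos, side="left", te="TE_A", clip=None, strand="-", qname=None,
            start=0, end=100, chrom="chr1", origin="unsplit"):
    return SupportingRead(
        qname=qname or f"r{pos}_{side}", chrom=chrom, anchor_pos=pos, side=side,
        origin=origin, hit=make_hit(te, start, end, strand), clip_site=clip,
        is_chimera_truth=False,
    )


class TestClustering:
    def test_same_side_within_f95_clusters(self):
        reads = [make_sr(1000), make_sr(1400)]
        assert len(cluster_supporting_reads(reads, F95)) == 1

    def test_opposite_sides_within_2f95_clusters(self):
        reads = [make_sr(1000, "left"), make_sr(1900, "right")]
        assert len(cluster_supporting_reads(reads, F95)) == 1

    def test_same_side_beyond_f95_splits(self):
        reads = [make_sr(1000), make_sr(1500)]
        assert len(cluster_supporting_reads(reads, F95)) == 2

    def test_single_linkage_chain(self):
        reads = [make_sr(1000), make_sr(1400), make_sr(1800)]
        clusters = cluster_supporting_reads(reads, F95)
        assert len(clusters) == 1 and len(clusters[0]) == 3

    def test_families_never_chain(self):
        reads = [make_sr(1000, te="TE_A"), make_sr(1100, te="TE_B")]
        assert len(cluster_supporting_reads(reads, F95)) == 2

    def test_chromosomes_never_chain(self):
        reads = [make_sr(1000, chrom="chr1"), make_sr(1000, chrom="chr2")]
        assert len(cluster_supporting_reads(reads, F95)) == 2

    @staticmethod
    def _oracle(reads, f95):
        """Brute-force transitive closure over the pairwise linking rule."""
        n = len(reads)
        adj = {i: set() for i in range(n)}
        for i, j in itertools.combinations(range(n), 2):
            a, b = reads[i], reads[j]
            d = abs(a.anchor_pos - b.anchor_pos)
            linked = d < f95 if a.side == b.side else d < 2 * f95
            if linked:
                adj[i].add(j)
                adj[j].add(i)
        seen, comps = set(), []
        for i in range(n):
            if i in seen:
                continue
            stack, comp = [i], set()
            while stack:
                k = stack.pop()
                if k in comp:
                    continue
                comp.add(k)
                stack.extend(adj[k] - comp)
            seen |= comp
            comps.append(frozenset(reads[k].qname for k in comp))
        return set(comps)

    @given(
        st.lists(
            st.tuples(st.integers(0, 5000), st.booleans()),
            min_size=1, max_size=50,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_transitive_closure_oracle(self, spec):
        reads = [
            make_sr(pos, "left" if left else "right", qname=f"q{i}")
            for i, (pos, left) in enumerate(spec)
        ]
        got = {
            frozenset(r.qname for r in cl)
            for cl in cluster_supporting_reads(reads, F95)
        }
        assert got == self._oracle(reads, F95)

    def test_every_read_in_exactly_one_cluster(self):
        reads = [make_sr(p, qname=f"q{i}") for i, p in enumerate(range(0, 5000, 300))]
        clusters = cluster_supporting_reads(reads, F95)
        names = [r.qname for cl in clusters for r in cl]
        assert sorted(names) == sorted(r.qname for r in reads)


class TestBreakpoint:
    def test_modal_clip_site(self):
        reads = (
            [make_sr(10_000, clip=10_000, origin="split") for _ in range(3)]
            + [make_sr(10_002, clip=10_002, origin="split")]
        )
        assert call_breakpoint(reads) == 10_000

    def test_clip_tie_goes_to_smallest(self):
        reads = [
            make_sr(10_002, clip=10_002), make_sr(10_000, clip=10_000),
        ]
        assert call_breakpoint(reads) == 10_000

    def test_mean_of_anchor_ends_without_clips(self):
        reads = [make_sr(9_990, "left"), make_sr(10_010, "right")]
        assert call_breakpoint(reads) == 10_000

    def test_rounding_half_up(self):
        reads = [make_sr(10), make_sr(11), make_sr(12), make_sr(13)]
        assert call_breakpoint(reads) == 12  # mean 11.5 rounds up

    def test_single_read(self):
        assert call_breakpoint([make_sr(5000)]) == 5000


class TestClassify:
    def test_both_sides_is_1p1(self):
        reads = [make_sr(1000, "left")] * 3 + [make_sr(1100, "right")] * 2
        assert classify_cluster(reads) == "1p1"

    def test_one_side_multiple_is_2p(self):
        assert classify_cluster([make_sr(1000, "left")] * 4) == "2p"

    def test_single_read_is_singleton(self):
        assert classify_cluster([make_sr(1000)]) == "singleton"


class TestFrequency:
    @pytest.mark.parametrize(
        "S,R,expected",
        [(10, 10, 1 / 3), (5, 0, 1.0), (1, 49, 1 / 99)],
    )
    def test_printed_equation(self, S, R, expected):
        assert estimate_insertion_frequency(S, R) == pytest.approx(expected, abs=1e-4)

    def test_undefined_without_support(self):
        with pytest.raises(ValueError):
            estimate_insertion_frequency(0, 10)

    @given(st.integers(1, 500), st.integers(0, 500))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_S_and_R(self, S, R):
        p = estimate_insertion_frequency(S, R)
        assert 0 < p <= 1
        assert estimate_insertion_frequency(S + 1, R) > p or R == 0
        assert estimate_insertion_frequency(S, R + 1) < p


class TestTeEnds:
    def test_envelope_of_two_end_hits(self):
        reads = [
            make_sr(1000, start=0, end=95),
            make_sr(1100, "right", start=4900, end=4980, strand="+"),
        ]
        assert predict_te_ends(reads) == (0, 4980)

    def test_single_hit(self):
        assert predict_te_ends([make_sr(1000, start=200, end=290)]) == (200, 290)

    def test_hits_on_both_strands_enumeration_oracle(self):
        # hits are reported on forward-consensus coordinates regardless of
        # read strand, so the envelope is the plain min/max — check against
        # explicit enumeration
        reads = [
            make_sr(1000, start=0, end=90, strand="-"),
            make_sr(1010, start=40, end=140, strand="+"),
            make_sr(1600, "right", start=4800, end=4900, strand="+"),
        ]
        coords = [(r.hit.hit_start, r.hit.hit_end) for r in reads]
        oracle = (min(c[0] for c in coords), max(c[1] for c in coords))
        assert predict_te_ends(reads) == oracle


class TestReferenceReads:
    def _readset(self, frags, chrom="chr1"):
        import numpy as np

        from tescan.readpairs import BulkPairs, ReadSet

        starts = np.array([s for s, _ in frags], dtype=np.int64)
        ends = np.array([e for _, e in frags], dtype=np.int64)
        bulk = BulkPairs(
            chrom_id=np.zeros(len(frags), dtype=np.int32),
            start1=starts, end1=starts + 100,
            start2=ends - 100, end2=ends,
            tlen=ends - starts,
            proper=np.ones(len(frags), dtype=bool),
        )
        return ReadSet([chrom], {chrom: 100_000}, bulk, [])

    def test_fragment_crossing_margins(self):
        from tescan.calling import ReferenceReadCounter

        bp = 5000
        frags = [
            (bp - 250, bp + 250),  # crosses generously -> counts
            (bp - 20, bp + 400),  # exactly 20 on the left -> excluded
            (bp - 400, bp + 20),  # exactly 20 on the right -> excluded
            (bp - 21, bp + 21),  # just over the margin -> counts
            (bp + 30, bp + 480),  # right of the breakpoint -> excluded
        ]
        counter = ReferenceReadCounter(self._readset(frags))
        assert counter.count("chr1", bp) == 2

    def test_other_chromosome_zero(self):
        from tescan.calling import ReferenceReadCounter

        counter = ReferenceReadCounter(self._readset([(100, 600)]))
        assert counter.count("chr9", 300) == 0
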