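import numpy as np
import pytest

from tescan import (
    ConsensusAligner,
    ConsensusLibrary,
    define_end_regions,
    estimate_de_novo,
    expected_singleton_yield,
    tally_end_center,
)
from tescan.denovo import EndCenterTally, include_fragmented_copies
from tescan.readpairs import extract_candidates
from tescan.simulate import (
    ReadSimParams,
    _build_event_context,
    _event_fragment_pair,
    _random_dna,
    _revcomp,
)

from test_calling import make_hit, make_sr


@pytest.fixture(scope="module")
def library():
    rng = np.random.default_rng(21)
    return ConsensusLibrary({"TE_A": _random_dna(rng, 5000), "TE_S": _random_dna(rng, 800)})


class TestEndRegions:
    def test_substitution(self, library):
        spec = define_end_regions(library, f95=466)
        reg = spec.regions["TE_A"]
        assert spec.l_end == 441
        assert reg.center_defined
        assert (reg.end_intervals[0][:2], reg.end_intervals[1][:2]) == (
            (0, 441), (4559, 5000),
        )

    def test_short_transposon_center_undefined(self, library):
        spec = define_end_regions(library, f95=466)
        assert not spec.regions["TE_S"].center_defined

    def test_degenerate_but_valid_l_end(self, library):
        spec = define_end_regions(library, f95=26)
        assert spec.l_end == 1
        assert spec.regions["TE_A"].center_defined

    def test_no_end_region_errors(self, library):
        with pytest.raises(ValueError):
            define_end_regions(library, f95=20)


class TestOrientationGeometry:
    """The simulator provides the oracle: reads generated at a true
    insertion junction must classify as end-mapping under the orientation
    check, for every insertion orientation and junction side."""

    @pytest.mark.parametrize("sigma", ["+", "-"])
    def test_true_junction_reads_are_oriented_end(self, sigma, library):
        rng = np.random.default_rng(3)
        params = ReadSimParams(error_rate=0.0)
        insert = library.entries["TE_A"] if sigma == "+" else _revcomp(
            library.entries["TE_A"]
        )
        ctx = _build_event_context(
            _random_dna(rng, 600), _random_dna(rng, 600), insert, "chr1", 50_000, 0
        )
        pairs = []
        for k in range(120):
            frag = int(round(rng.normal(450, 10)))
            # straddle either junction
            h = int(rng.integers(-frag + 30, 30)) if k % 2 else int(
                rng.integers(len(insert) - frag + 30, len(insert) - 30)
            )
            pairs.append(_event_fragment_pair(ctx, h, frag, params, rng, f"q{k}"))
        cands = extract_candidates(pairs)
        assert len(cands) > 50
        aligner = ConsensusAligner(library)
        spec = define_end_regions(library, f95=466)
        seen = set()
        for cand in cands:
            hit = aligner.align(cand.seq)
            if hit is None:
                continue
            seen.add((cand.side, hit.strand))
            assert spec.regions["TE_A"].oriented_end(hit), (
                cand.side, hit.strand, hit.hit_start, hit.hit_end, sigma,
            )
        # both sides are observed, each with a single consistent strand
        assert {s for s, _ in seen} == {"left", "right"}
        assert len(seen) == 2

    def test_wrong_orientation_counts_as_center(self, library):
        spec = define_end_regions(library, f95=466)
        reg = spec.regions["TE_A"]
        near_start_fwd = make_hit("TE_A", 100, 200, "+")
        near_start_rev = make_hit("TE_A", 100, 200, "-")
        assert not reg.oriented_end(near_start_fwd)
        assert reg.oriented_end(near_start_rev)
        assert reg.positional_end(near_start_fwd)  # AE stays positional


class TestTally:
    def test_positional_classification(self, library):
        spec = define_end_regions(library, f95=466)
        singles = [
            make_sr(1000, start=100, end=200, strand="-", te="TE_A"),  # end
            make_sr(2000, start=2000, end=2100, strand="-", te="TE_A"),  # center
        ]
        tallies = tally_end_center(singles, [], spec, library)
        assert (tallies["TE_A"].SE, tallies["TE_A"].SC) == (1, 1)

    def test_all_read_tallies_positional_only(self, library):
        spec = define_end_regions(library, f95=466)
        hits = [
            make_hit("TE_A", 100, 200, "+"),  # wrong strand, still AE
            make_hit("TE_A", 2000, 2100, "-"),
            make_hit("TE_A", 4600, 4700, "+"),
        ]
        tallies = tally_end_center([], hits, spec, library)
        assert (tallies["TE_A"].AE, tallies["TE_A"].AC) == (2, 1)


class TestEstimate:
    def _tally(self, family="TE_A", **kw):
        defaults = dict(SE=0, SC=0, AE=0, AC=0, center_defined=True)
        defaults.update(kw)
        return {family: EndCenterTally(family=family, **defaults)}

    def test_substitution(self):
        est = estimate_de_novo(
            self._tally(SE=10, SC=2, AE=50, AC=50), r_exp=1.0, n_genomes=1
        )["TE_A"]
        assert est.d_reads == pytest.approx(8.0)
        assert est.confidence == pytest.approx(0.8)

    def test_background_only_family_floors_at_zero(self):
        est = estimate_de_novo(
            self._tally(SE=5, SC=10, AE=50, AC=50), r_exp=1.0, n_genomes=1
        )["TE_A"]
        assert est.d_reads == 0.0
        assert est.d_raw == pytest.approx(-5.0)
        assert est.confidence == 0.0

    def test_no_center_reads_leaves_estimate_uncorrected(self):
        est = estimate_de_novo(
            self._tally(SE=5, SC=0, AE=50, AC=0), r_exp=1.0, n_genomes=1
        )["TE_A"]
        assert est.d_reads == 5.0
        assert not est.corrected

    def test_zero_evidence_family_is_zero(self):
        est = estimate_de_novo(self._tally(), r_exp=1.0, n_genomes=10)["TE_A"]
        assert est.insertions_per_genome == 0.0
        assert est.confidence == 0.0

    def test_confidence_monotone_decreasing_in_SC(self):
        last = 1.1
        for sc in range(0, 12):
            est = estimate_de_novo(
                self._tally(SE=10, SC=sc, AE=50, AC=50), r_exp=1.0, n_genomes=1
            )["TE_A"]
            assert 0.0 <= est.confidence <= 1.0
            assert est.confidence <= last
            last = est.confidence

    def test_analytic_yield_formula(self):
        # d=0.002, span 450-30=420, reads/bp d/(2*100), two junctions
        assert expected_singleton_yield(0.002) == pytest.approx(0.0084)


class TestChimeraUnbiasedness:
    def test_uniform_chimeras_give_zero_mean_correction(self, library):
        """Pure chimera background: reads placed uniformly on the
        consensus, no true insertions.  The unclamped corrected count
        D_raw = SE - SC*(AE/AC) has mean within 3 standard errors of 0
        over 150 replicates."""
        rng = np.random.default_rng(17)
        spec = define_end_regions(library, f95=466)
        L = 5000
        d_raws = []
        for _ in range(150):
            # independent singleton and all-read samples, uniform positions
            def uniform_hits(n):
                starts = rng.integers(0, L - 100, size=n)
                strands = np.where(rng.integers(0, 2, n) == 0, "+", "-")
                return [
                    make_hit("TE_A", int(s), int(s) + 100, str(st))
                    for s, st in zip(starts, strands)
                ]

            singles = [
                make_sr(1000 + 600 * i, te="TE_A", qname=f"s{i}")
                for i in range(60)
            ]
            for sr, hit in zip(singles, uniform_hits(60)):
                sr.hit = hit
            tallies = tally_end_center(
                singles, uniform_hits(600), spec, library, orientation_check=False
            )
            est = estimate_de_novo(tallies, r_exp=1.0, n_genomes=1)["TE_A"]
            d_raws.append(est.d_raw)
        d = np.array(d_raws)
        sem = d.std(ddof=1) / np.sqrt(len(d))
        assert abs(d.mean()) <= 3 * sem


class TestFragmentedCopies:
    def _singles_near(self, te, pos, n, strand):
        if strand == "-":
            return [
                make_sr(1000 + i, te=te, start=pos, end=pos + 100, strand="-",
                        qname=f"f{pos}_{i}")
                for i in range(n)
            ]
        return [
            make_sr(1000 + i, te=te, start=pos - 100, end=pos, strand="+",
                    qname=f"r{pos}_{i}")
            for i in range(n)
        ]

    def test_supported_fragment_ends_enter_tally(self, library):
        spec = define_end_regions(library, f95=466)
        # fragment spanning consensus [1500, 3500): its ends are center
        # positions of the full-length consensus
        singles = (
            self._singles_near("TE_A", 1500, 3, "-")
            + self._singles_near("TE_A", 3500, 3, "+")
        )
        spec2 = include_fragmented_copies(
            spec, [("TE_A", 1500, 3500)], singles, library, min_support=3
        )
        tallies = tally_end_center(singles, [], spec2, library)
        assert tallies["TE_A"].SE == 6
        # without the fragment they'd all be center
        base = tally_end_center(singles, [], spec, library)
        assert base["TE_A"].SE == 0

    def test_insufficient_support_excluded(self, library):
        spec = define_end_regions(library, f95=466)
        singles = (
            self._singles_near("TE_A", 1500, 2, "-")
            + self._singles_near("TE_A", 3500, 3, "+")
        )
        spec2 = include_fragmented_copies(
            spec, [("TE_A", 1500, 3500)], singles, library, min_support=3
        )
        assert spec2.regions["TE_A"].end_intervals == spec.regions["TE_A"].end_intervals

    def test_mode_off_leaves_tallies_unchanged(self, library):
        spec = define_end_regions(library, f95=466)
        singles = self._singles_near("TE_A", 1500, 5, "-")
        base = tally_end_center(singles, [], spec, library)
        again = tally_end_center(singles, [], spec, library)
        assert base["TE_A"] == again["TE_A"]
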