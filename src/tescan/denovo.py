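"""Genome-wide de novo insertion rate estimation with chimera correction.

Reads that truly support new transposon insertions are confined to the
two *ends* of a consensus — as far inside as the library fragment length
allows — and enter the transposon in a fixed orientation, while chimeric
read pairs formed during library construction hit the consensus uniformly
on both strands.  The end of a transposon is defined as the 95th
percentile fragment length minus 25 nt (L_end); reads in the remaining
*center* estimate the chimera background.  The corrected count of de novo
supporting reads for a family is

    D = singleton end reads - singleton center reads * (all end reads /
                                                        all center reads)

and the estimated number of insertions is D divided by the expected
singleton-read yield of a single insertion present in one genome
(``r_exp``), which can be computed analytically from the library geometry
or calibrated empirically with the read simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .consensus import ConsensusHit, SupportingRead
from .io import ConsensusLibrary

END_OFFSET = 25  # nt subtracted from f95 to define the transposon end


# ---------------------------------------------------------------------------
# End / center regions
# ---------------------------------------------------------------------------

@dataclass
class TERegions:
    """End and center intervals of one consensus.

    Each end interval carries the consensus strand a *bona fide*
    insertion-supporting read must match there: reads entering through
    the consensus start align to the reverse strand, reads entering
    through the terminus align forward.
    """

    length: int
    l_end: int
    center_defined: bool
    end_intervals: list[tuple[int, int, str | None]] = field(default_factory=list)

    def positional_end(self, hit: ConsensusHit) -> bool:
        mid = (hit.hit_start + hit.hit_end) / 2
        return any(lo <= mid < hi for lo, hi, _ in self.end_intervals)

    def oriented_end(self, hit: ConsensusHit) -> bool:
        mid = (hit.hit_start + hit.hit_end) / 2
        return any(
            lo <= mid < hi and (strand is None or strand == hit.strand)
            for lo, hi, strand in self.end_intervals
        )


@dataclass
class EndRegionSpec:
    l_end: int
    regions: dict[str, TERegions]

    def for_hit(self, hit: ConsensusHit) -> TERegions:
        return self.regions[hit.transposon]


def define_end_regions(library: ConsensusLibrary, f95: float) -> EndRegionSpec:
    """Per-transposon end intervals [0, L_end) and [len - L_end, len) with
    L_end = f95 - 25; transposons shorter than 2 L_end have no center."""
    l_end = int(round(f95)) - END_OFFSET
    if l_end <= 0:
        raise ValueError(f"f95={f95} leaves no end region")
    regions = {}
    for name, seq in library.entries.items():
        length = len(seq)
        if length > 2 * l_end:
            regions[name] = TERegions(
                length=length,
                l_end=l_end,
                center_defined=True,
                end_intervals=[(0, l_end, "-"), (length - l_end, length, "+")],
            )
        else:
            # the whole consensus counts as end; center is undefined and
            # no chimera background can be estimated for this transposon
            regions[name] = TERegions(
                length=length,
                l_end=l_end,
                center_defined=False,
                end_intervals=[(0, length, None)],
            )
    return EndRegionSpec(l_end, regions)


# ---------------------------------------------------------------------------
# Tallies
# ---------------------------------------------------------------------------

@dataclass
class EndCenterTally:
    family: str
    SE: int = 0  # singleton end-mapping reads
    SC: int = 0  # singleton center-mapping reads
    AE: int = 0  # all end-mapping reads
    AC: int = 0  # all center-mapping reads
    center_defined: bool = True


def tally_end_center(
    singleton_reads: Sequence[SupportingRead],
    all_hits: Iterable[ConsensusHit],
    spec: EndRegionSpec,
    library: ConsensusLibrary,
    orientation_check: bool = True,
) -> dict[str, EndCenterTally]:
    """Classify reads as end- or center-mapping, per transposon family.

    Singleton reads must additionally pass the orientation check (when
    enabled) to count as end-mapping; a wrong-orientation end hit is
    chimera evidence and counts as center.  The all-read tallies (AE/AC)
    are purely positional.
    """
    tallies: dict[str, EndCenterTally] = {}
    for family in library.families():
        defined = any(
            spec.regions[name].center_defined for name in library.members(family)
        )
        tallies[family] = EndCenterTally(family=family, center_defined=defined)

    for read in singleton_reads:
        hit = read.hit
        reg = spec.for_hit(hit)
        t = tallies[hit.family]
        is_end = reg.oriented_end(hit) if orientation_check else reg.positional_end(hit)
        if is_end:
            t.SE += 1
        else:
            t.SC += 1
    for hit in all_hits:
        reg = spec.for_hit(hit)
        t = tallies[hit.family]
        if reg.positional_end(hit):
            t.AE += 1
        else:
            t.AC += 1
    return tallies


def include_fragmented_copies(
    spec: EndRegionSpec,
    fragment_spans: Sequence[tuple[str, int, int]],
    singleton_reads: Sequence[SupportingRead],
    library: ConsensusLibrary,
    min_support: int = 3,
) -> EndRegionSpec:
    """Fragmented-transposon mode (the '-T' option).

    A genomic transposon fragment spanning consensus [cs, ce) contributes
    its own two ends as additional end intervals, provided at least
    ``min_support`` singleton reads fall near each fragment end.  Returns
    a new EndRegionSpec; the input is untouched.
    """
    import copy

    out = copy.deepcopy(spec)
    l_end = spec.l_end
    for te, cs, ce in fragment_spans:
        if te not in out.regions:
            continue
        reg = out.regions[te]
        start_iv = (cs, min(ce, cs + l_end), "-")
        end_iv = (max(cs, ce - l_end), ce, "+")
        n_start = n_end = 0
        for read in singleton_reads:
            hit = read.hit
            if hit.transposon != te:
                continue
            mid = (hit.hit_start + hit.hit_end) / 2
            if start_iv[0] <= mid < start_iv[1]:
                n_start += 1
            if end_iv[0] <= mid < end_iv[1]:
                n_end += 1
        if n_start >= min_support and n_end >= min_support:
            reg.end_intervals.extend([start_iv, end_iv])
    return out


def discover_fragment_spans(
    singleton_reads: Sequence[SupportingRead],
    library: ConsensusLibrary,
    spec: EndRegionSpec,
    min_support: int = 3,
    edge_tolerance: int = 25,
) -> list[tuple[str, int, int]]:
    """Detect fragmented-transposon consensus spans from read evidence.

    A transposon fragment that is itself transposing produces singleton
    reads whose consensus hits pile up at the fragment's two boundaries
    with junction orientation: reverse-strand hits *starting* exactly at
    the fragment 5' boundary (split-read clips land base-exact there),
    forward-strand hits *ending* exactly at its 3' boundary.  A span is
    reported when at least ``min_support`` reads agree base-exactly on
    each boundary.  Boundaries within ``edge_tolerance`` of the
    full-length consensus ends are already covered by the standard end
    regions and are not reported.
    """
    from collections import Counter, defaultdict

    by_te: dict[str, list[SupportingRead]] = defaultdict(list)
    for read in singleton_reads:
        by_te[read.hit.transposon].append(read)
    spans: list[tuple[str, int, int]] = []
    for te in sorted(by_te):
        reads = by_te[te]
        length = len(library.entries[te])
        starts = Counter(r.hit.hit_start for r in reads if r.hit.strand == "-")
        ends = Counter(r.hit.hit_end for r in reads if r.hit.strand == "+")
        cand_starts = [p for p, n in starts.items() if n >= min_support]
        cand_ends = [p for p, n in ends.items() if n >= min_support]
        if not cand_starts or not cand_ends:
            continue
        cs = max(cand_starts, key=lambda p: (starts[p], -p))
        ce = max(cand_ends, key=lambda p: (ends[p], p))
        if ce - cs < spec.l_end:
            continue
        if cs <= edge_tolerance and ce >= length - edge_tolerance:
            continue  # this is just the full-length consensus
        spans.append((te, cs, ce))
    return spans


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

@dataclass
class DeNovoEstimate:
    family: str
    SE: int
    SC: int
    AE: int
    AC: int
    d_raw: float  # corrected singleton-end read count, unclamped
    d_reads: float  # max(0, d_raw)
    insertions_total: float
    insertions_per_genome: float
    confidence: float
    center_defined: bool = True
    corrected: bool = True  # False when AC == 0 left no chimera estimate


def expected_singleton_yield(
    coverage_per_genome: float,
    frag_mean: float = 450.0,
    read_length: int = 100,
    min_anchor: int = 20,
    min_clip: int = 10,
) -> float:
    """Analytic supporting-read yield of one insertion carried by a single
    genome sequenced at ``coverage_per_genome``.

    A junction-straddling fragment yields a supporting pair unless the
    junction cuts a read too close to its ends (shorter than the
    mappable anchor on one side, shorter than the usable clip on the
    other), so each junction supports fragments across f_mean -
    min_anchor - min_clip start positions at d/(2*l) fragments per base,
    and an insertion has two junctions.
    """
    span = frag_mean - min_anchor - min_clip
    return coverage_per_genome * span / read_length


def estimate_de_novo(
    tallies: Mapping[str, EndCenterTally],
    r_exp: float,
    n_genomes: int,
) -> dict[str, DeNovoEstimate]:
    """Convert end/center tallies into per-family insertion estimates."""
    if r_exp <= 0:
        raise ValueError("r_exp must be positive")
    out: dict[str, DeNovoEstimate] = {}
    for family in sorted(tallies):
        t = tallies[family]
        corrected = True
        if t.AC > 0:
            d_raw = t.SE - t.SC * (t.AE / t.AC)
        else:
            d_raw = float(t.SE)
            corrected = t.SE == 0
        d_reads = max(0.0, d_raw)
        if t.SE > 0:
            chimera_rate = min(1.0, (t.SE - d_raw) / t.SE)
            confidence = 1.0 - chimera_rate
        else:
            confidence = 0.0
        total = d_reads / r_exp
        out[family] = DeNovoEstimate(
            family=family,
            SE=t.SE,
            SC=t.SC,
            AE=t.AE,
            AC=t.AC,
            d_raw=d_raw,
            d_reads=d_reads,
            insertions_total=total,
            insertions_per_genome=total / n_genomes,
            confidence=confidence,
            center_defined=t.center_defined,
            corrected=corrected,
        )
    return out


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def collect_all_hits(result, readset) -> list[ConsensusHit]:
    """Hits of every consensus-mapped read: all supporting reads plus the
    genome-unanchored pairs (both mates unmapped, e.g. fully inside a
    transposon), aligned here with the caller's aligner."""
    hits = [r.hit for r in result.supporting_reads]
    aligner = result.aligner
    for pair in readset.iter_unanchored():
        for read in pair.reads:
            seq = read.read_oriented_seq()
            if seq is None:
                continue
            hit = aligner.align(seq)
            if hit is not None:
                hits.append(hit)
    return hits


def estimate_denovo_rates(
    result,
    readset,
    library: ConsensusLibrary,
    n_genomes: int,
    depth: float,
    r_exp: float | None = None,
    frag_mean: float | None = None,
    orientation_check: bool = True,
    fragment_spans: Sequence[tuple[str, int, int]] | None = None,
    discover_fragments: bool = False,
    min_fragment_support: int = 3,
) -> dict[str, DeNovoEstimate]:
    """Full de novo estimation from a caller result.

    ``r_exp`` defaults to the analytic yield for the library geometry;
    pass a simulator-calibrated value for sharper absolute rates.  With
    ``discover_fragments`` (the '-T' mode without an annotation),
    fragmented-transposon spans are inferred from the singleton reads
    themselves.
    """
    spec = define_end_regions(library, result.f95)
    singles = result.singleton_reads()
    if discover_fragments and fragment_spans is None:
        fragment_spans = discover_fragment_spans(
            singles, library, spec, min_fragment_support
        )
    if fragment_spans:
        spec = include_fragmented_copies(
            spec, fragment_spans, singles, library, min_fragment_support
        )
    all_hits = collect_all_hits(result, readset)
    tallies = tally_end_center(
        singles, all_hits, spec, library, orientation_check=orientation_check
    )
    if r_exp is None:
        if frag_mean is None:
            frag_mean = result.f95 - 1.645 * 10.0  # crude fallback
        r_exp = expected_singleton_yield(
            depth / n_genomes, frag_mean, readset.read_length
        )
    return estimate_de_novo(tallies, r_exp, n_genomes)


def calibrate_singleton_yield(
    f95: float,
    coverage_per_genome: float,
    read_length: int = 100,
    frag_mean: float = 450.0,
    frag_sd: float = 10.0,
    error_rate: float = 0.001,
    n_events: int = 200_000,
    read_density: float | None = None,
    seed: int = 0,
) -> float:
    """Empirical r_exp: simulate single-genome insertions with the read
    simulator, run the caller, and count surviving singleton end reads
    per insertion.

    ``read_density`` (supporting reads per bp of genome) spreads the
    simulated events so that the occasional clustering of nearby
    singleton reads — which removes them from the singleton tally — is
    reproduced at the density of the dataset being analysed.
    """
    from .simulate import simulate_calibration_events

    return simulate_calibration_events(
        f95=f95,
        coverage_per_genome=coverage_per_genome,
        read_length=read_length,
        frag_mean=frag_mean,
        frag_sd=frag_sd,
        error_rate=error_rate,
        n_events=n_events,
        read_density=read_density,
        seed=seed,
    )
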