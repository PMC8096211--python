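"""Clustering of supporting reads into insertion calls.

Two supporting reads join the same cluster when they are on the same side
of a putative insertion and closer than the 95th-percentile fragment
length (f95), or on opposite sides and closer than twice f95 —
single-linkage, per chromosome and per transposon family.  Clusters are
classified by the sides that support them (1p1 / 2p / singleton), the
breakpoint is the modal soft-clip site of split reads (falling back to
the mean 3'-end of the anchors), and the insertion frequency is
S / (S + 2R), with S the supporting reads of the cluster and R the
properly mapped, unsplit read pairs whose fragment crosses the
breakpoint by more than 20 bp on each side.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .consensus import ConsensusAligner, SupportingRead
from .io import ConsensusLibrary, RepeatAnnotation
from .readpairs import (
    DEFAULT_MAPQ_UNIQUE,
    DEFAULT_MIN_CLIP,
    PairClass,
    ReadSet,
    classify_pair,
)

BREAKPOINT_MARGIN = 20  # bp a reference fragment must cross on each side


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _pair_links(a: SupportingRead, b: SupportingRead, f95: float) -> bool:
    d = abs(a.anchor_pos - b.anchor_pos)
    if a.side == b.side:
        return d < f95
    return d < 2 * f95


def cluster_supporting_reads(
    reads: Sequence[SupportingRead], f95: float, per_family: bool = True
) -> list[list[SupportingRead]]:
    """Single-linkage clustering under the two distance rules.

    Clusters never span chromosomes; with ``per_family`` (default) they
    never span transposon families either, which prevents unrelated
    families from chaining through a shared locus (co-located families
    are reconciled later by the same-position merge).
    """
    groups: dict[tuple, list[SupportingRead]] = defaultdict(list)
    for r in reads:
        key = (r.chrom, r.family) if per_family else (r.chrom,)
        groups[key].append(r)

    clusters: list[list[SupportingRead]] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda r: (r.anchor_pos, r.qname))
        n = len(members)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i: int, j: int) -> None:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri

        limit = 2 * f95
        for i in range(n):
            for j in range(i + 1, n):
                if members[j].anchor_pos - members[i].anchor_pos >= limit:
                    break
                if _pair_links(members[i], members[j], f95):
                    union(i, j)
        by_root: dict[int, list[SupportingRead]] = defaultdict(list)
        for i, r in enumerate(members):
            by_root[find(i)].append(r)
        for root in sorted(by_root):
            clusters.append(by_root[root])
    return clusters


# ---------------------------------------------------------------------------
# Per-cluster calls
# ---------------------------------------------------------------------------

def call_breakpoint(cluster: Sequence[SupportingRead]) -> int:
    """Breakpoint of a cluster: modal soft-clip site (ties to the smallest
    coordinate), else the mean anchor 3'-end rounded half-up."""
    if not cluster:
        raise ValueError("empty cluster")
    clip_sites = [r.clip_site for r in cluster if r.clip_site is not None]
    if clip_sites:
        counts = Counter(clip_sites)
        best = max(counts.values())
        return min(site for site, n in counts.items() if n == best)
    mean = sum(r.anchor_pos for r in cluster) / len(cluster)
    return int(math.floor(mean + 0.5))


def classify_cluster(cluster: Sequence[SupportingRead]) -> str:
    if not cluster:
        raise ValueError("empty cluster")
    if len(cluster) == 1:
        return "singleton"
    sides = {r.side for r in cluster}
    return "1p1" if len(sides) == 2 else "2p"


def predict_te_ends(cluster: Sequence[SupportingRead]) -> tuple[int, int]:
    """Envelope of the consensus hits: predicted extent of the inserted
    transposon on its consensus (forward-strand coordinates)."""
    starts = [r.hit.hit_start for r in cluster]
    ends = [r.hit.hit_end for r in cluster]
    return min(starts), max(ends)


def _implied_insertion_strand(read: SupportingRead) -> str:
    """Orientation of the inserted transposon implied by one read.

    A left-side anchor whose candidate matches the reverse strand of the
    consensus entered through the consensus 5' start: plus insertion.
    The other three side/strand combinations follow by symmetry.
    """
    if read.side == "left":
        return "+" if read.hit.strand == "-" else "-"
    return "+" if read.hit.strand == "+" else "-"


def estimate_insertion_frequency(S: int, R: int) -> float:
    """Insertion frequency p = S / (S + 2R).

    S is the number of transposon-supporting read pairs of the call, R
    the breakpoint-crossing reference pairs; each insertion contributes
    supporting reads from both junctions while a reference fragment
    crosses the locus once, hence the factor two.
    """
    if S < 1:
        raise ValueError("frequency undefined without supporting reads")
    if R < 0:
        raise ValueError("negative reference count")
    return S / (S + 2 * R)


@dataclass
class InsertionCall:
    chrom: str
    breakpoint: int
    transposon: str
    family: str
    strand: str
    insertion_class: str  # '1p1' | '2p' | 'singleton'
    reads_left: list[SupportingRead]
    reads_right: list[SupportingRead]
    te_start: int
    te_end: int
    n_reference: int = 0
    frequency: float = float("nan")
    filter_flags: list[str] = field(default_factory=list)

    @property
    def n_support(self) -> int:
        return len(self.reads_left) + len(self.reads_right)

    @property
    def reads(self) -> list[SupportingRead]:
        return self.reads_left + self.reads_right

    @property
    def n_support_5p(self) -> int:
        """Reads supporting the transposon's 5' junction (strand-aware)."""
        left, right = len(self.reads_left), len(self.reads_right)
        return left if self.strand == "+" else right

    @property
    def n_support_3p(self) -> int:
        left, right = len(self.reads_left), len(self.reads_right)
        return right if self.strand == "+" else left


def build_call(cluster: Sequence[SupportingRead]) -> InsertionCall:
    """Assemble an InsertionCall from one cluster (frequency comes later)."""
    breakpoint = call_breakpoint(cluster)
    cls = classify_cluster(cluster)
    te_start, te_end = predict_te_ends(cluster)
    te_counts = Counter(r.hit.transposon for r in cluster)
    best = max(te_counts.values())
    transposon = min(t for t, n in te_counts.items() if n == best)
    family = cluster[0].family
    strand_votes = Counter(_implied_insertion_strand(r) for r in cluster)
    strand = "+" if strand_votes["+"] >= strand_votes["-"] else "-"
    return InsertionCall(
        chrom=cluster[0].chrom,
        breakpoint=breakpoint,
        transposon=transposon,
        family=family,
        strand=strand,
        insertion_class=cls,
        reads_left=[r for r in cluster if r.side == "left"],
        reads_right=[r for r in cluster if r.side == "right"],
        te_start=te_start,
        te_end=te_end,
    )


# ---------------------------------------------------------------------------
# Reference reads
# ---------------------------------------------------------------------------

class ReferenceReadCounter:
    """Counts properly mapped, unsplit pairs whose fragment extends more
    than ``margin`` bp on both sides of a breakpoint."""

    def __init__(
        self,
        readset: ReadSet,
        margin: int = BREAKPOINT_MARGIN,
        mapq_unique: int = DEFAULT_MAPQ_UNIQUE,
        min_clip: int = DEFAULT_MIN_CLIP,
    ):
        self.margin = margin
        frag_parts: dict[str, list[np.ndarray]] = defaultdict(list)
        bulk = readset.bulk
        if len(bulk):
            proper = bulk.proper
            fs = bulk.frag_start[proper]
            fe = bulk.frag_end[proper]
            cid = bulk.chrom_id[proper]
            for ci in np.unique(cid):
                mask = cid == ci
                chrom = readset.chroms[int(ci)]
                frag_parts[chrom].append(np.stack([fs[mask], fe[mask]], axis=1))
        extra: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for pair in readset.featured:
            cls, _ = classify_pair(pair, mapq_unique, min_clip)
            if cls is not PairClass.PROPER:
                continue
            r1, r2 = pair.reads
            if max(r1.clip_left, r1.clip_right, r2.clip_left, r2.clip_right) >= min_clip:
                continue  # clipped pairs are not 'unsplit'
            extra[r1.chrom].append(
                (min(r1.pos, r2.pos), max(r1.reference_end, r2.reference_end))
            )
        for chrom, pairs in extra.items():
            frag_parts[chrom].append(np.array(pairs, dtype=np.int64).reshape(-1, 2))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._max_len = 1
        for chrom, parts in frag_parts.items():
            arr = np.concatenate(parts, axis=0)
            order = np.argsort(arr[:, 0], kind="stable")
            self._starts[chrom] = arr[order, 0]
            self._ends[chrom] = arr[order, 1]
            if arr.size:
                self._max_len = max(self._max_len, int((arr[:, 1] - arr[:, 0]).max()))

    def count(self, chrom: str, breakpoint: int) -> int:
        starts = self._starts.get(chrom)
        if starts is None or starts.size == 0:
            return 0
        ends = self._ends[chrom]
        m = self.margin
        hi = np.searchsorted(starts, breakpoint - m, side="left")
        lo = np.searchsorted(starts, breakpoint - m - self._max_len, side="left")
        return int(np.count_nonzero(ends[lo:hi] > breakpoint + m))


def count_reference_reads(
    call: InsertionCall, counter: ReferenceReadCounter
) -> int:
    return counter.count(call.chrom, call.breakpoint)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class CallerConfig:
    """Tunable parameters of the caller, with the defaults used throughout."""

    mapq_unique: int = DEFAULT_MAPQ_UNIQUE
    min_clip: int = DEFAULT_MIN_CLIP
    max_divergence: float = 0.10
    min_aligned: int = 20
    min_support: int = 5
    f95: float | None = None
    window_size: int = 1000
    coverage_ratio: float = 5.0
    coverage_filter: bool = True
    genome_count: int | None = None
    freq_threshold: float | None = None

    def de_novo_threshold(self) -> float | None:
        """Frequency below which a call is a de novo candidate.

        With a known genome count g the threshold is twice the theoretical
        frequency of a single-genome insertion, 2/g; otherwise only
        singletons are de novo candidates (threshold None).
        """
        if self.freq_threshold is not None:
            return self.freq_threshold
        if self.genome_count:
            return 2.0 / self.genome_count
        return None


@dataclass
class CallResult:
    calls: list[InsertionCall]  # all surviving calls, singletons included
    removed: list[InsertionCall]
    f95: float
    config: CallerConfig
    supporting_reads: list[SupportingRead]
    aligner: ConsensusAligner

    def germline_calls(self, min_support: int | None = None) -> list[InsertionCall]:
        """1p1 and 2p calls at or above the supporting-read cutoff."""
        if min_support is None:
            min_support = self.config.min_support
        thr = self.config.de_novo_threshold()
        out = []
        for c in self.calls:
            if c.insertion_class == "singleton":
                continue
            if c.n_support < min_support:
                continue
            if thr is not None and c.frequency < thr:
                continue
            out.append(c)
        return out

    def de_novo_candidates(self) -> list[InsertionCall]:
        thr = self.config.de_novo_threshold()
        if thr is None:
            return [c for c in self.calls if c.insertion_class == "singleton"]
        return [c for c in self.calls if c.frequency < thr]

    def singleton_reads(self) -> list[SupportingRead]:
        return [
            r for c in self.calls if c.insertion_class == "singleton" for r in c.reads
        ]


def call_insertions(
    readset: ReadSet,
    library: ConsensusLibrary,
    annotation: RepeatAnnotation | None = None,
    config: CallerConfig | None = None,
    aligner: ConsensusAligner | None = None,
) -> CallResult:
    """Run the full caller: classify, align, cluster, call, filter."""
    from .filtering import apply_filters  # local import to avoid a cycle

    config = config or CallerConfig()
    f95 = config.f95
    if f95 is None:
        f95 = readset.fragment_model().f95

    candidates = readset.candidates(config.mapq_unique, config.min_clip)
    if aligner is None:
        aligner = ConsensusAligner(
            library,
            max_divergence=config.max_divergence,
            min_aligned=config.min_aligned,
        )
    from .consensus import assign_supporting_reads

    supports = assign_supporting_reads(candidates, aligner=aligner)
    clusters = cluster_supporting_reads(supports, f95)
    calls = [build_call(c) for c in clusters]

    kept, removed = apply_filters(
        calls,
        annotation=annotation,
        readset=readset if config.coverage_filter else None,
        library=library,
        window_size=config.window_size,
        coverage_ratio=config.coverage_ratio,
    )

    counter = ReferenceReadCounter(
        readset, mapq_unique=config.mapq_unique, min_clip=config.min_clip
    )
    for call in kept:
        call.n_reference = counter.count(call.chrom, call.breakpoint)
        call.frequency = estimate_insertion_frequency(call.n_support, call.n_reference)

    kept.sort(key=lambda c: (c.chrom, c.breakpoint, c.transposon))
    return CallResult(
        calls=kept,
        removed=removed,
        f95=f95,
        config=config,
        supporting_reads=supports,
        aligner=aligner,
    )
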