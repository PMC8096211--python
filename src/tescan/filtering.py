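"""False-positive filters applied immediately after calling.

Three filters run in order: (1) insertions of a transposon into an
annotated copy of the same transposon or family are discarded and their
positions blacklisted for every family; (2) insertions in genomic windows
whose sequencing depth is at least five times the genome mean are
discarded; (3) calls at exactly the same breakpoint are merged, assigning
all supporting reads to the transposon with the most reads.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .calling import InsertionCall
from .io import ConsensusLibrary, RepeatAnnotation
from .readpairs import ReadSet

DEFAULT_WINDOW_SIZE = 1000
DEFAULT_COVERAGE_RATIO = 5.0


@dataclass
class Blacklist:
    """Genomic positions of filtered same-transposon insertions.

    Any later call at a blacklisted position is removed regardless of its
    family — co-located calls usually come from related subfamilies and
    share the alignment artifact.
    """

    positions: set[tuple[str, int]] = field(default_factory=set)

    def add(self, chrom: str, pos: int) -> None:
        self.positions.add((chrom, pos))

    def __contains__(self, item: tuple[str, int]) -> bool:
        return item in self.positions


def filter_same_transposon(
    calls: list[InsertionCall],
    annotation: RepeatAnnotation,
    library: ConsensusLibrary | None = None,
    blacklist: Blacklist | None = None,
) -> tuple[list[InsertionCall], list[InsertionCall], Blacklist]:
    """Remove insertions into an annotated copy of the same transposon (or
    same family), blacklisting their positions for all families."""
    blacklist = blacklist or Blacklist()
    family_of = library.family_of if library is not None else {}
    removed: list[InsertionCall] = []
    survivors: list[InsertionCall] = []
    for call in calls:
        hit_same = False
        for iv in annotation.overlapping(call.chrom, call.breakpoint):
            if iv.name == call.transposon:
                hit_same = True
                break
            fam_ann = family_of.get(iv.name, iv.name)
            if fam_ann == call.family:
                hit_same = True
                break
        if hit_same:
            call.filter_flags.append("same_transposon")
            blacklist.add(call.chrom, call.breakpoint)
            removed.append(call)
        else:
            survivors.append(call)
    kept: list[InsertionCall] = []
    for call in survivors:
        if (call.chrom, call.breakpoint) in blacklist:
            call.filter_flags.append("blacklist")
            removed.append(call)
        else:
            kept.append(call)
    return kept, removed, blacklist


@dataclass
class CoverageProfile:
    """Read depth in fixed non-overlapping windows, used to flag regions
    whose depth is implausibly high (collapsed repeats, assembly gaps)."""

    window_size: int
    counts: dict[str, np.ndarray]
    read_length: int
    mean_depth: float

    @classmethod
    def from_readset(
        cls, readset: ReadSet, window_size: int = DEFAULT_WINDOW_SIZE
    ) -> "CoverageProfile":
        counts = {
            chrom: np.zeros(max(1, -(-length // window_size)), dtype=np.int64)
            for chrom, length in readset.chrom_lengths.items()
        }
        bulk = readset.bulk
        for starts in (bulk.start1, bulk.start2):
            for ci in np.unique(bulk.chrom_id):
                chrom = readset.chroms[int(ci)]
                if chrom not in counts:
                    counts[chrom] = np.zeros(1, dtype=np.int64)
                w = starts[bulk.chrom_id == ci] // window_size
                arr = counts[chrom]
                np.add.at(arr, np.clip(w, 0, arr.size - 1), 1)
        for pair in readset.featured:
            for read in pair.reads:
                if read.mapped and read.chrom in counts:
                    arr = counts[read.chrom]
                    w = min(read.pos // window_size, arr.size - 1)
                    arr[w] += 1
        total_reads = int(sum(int(a.sum()) for a in counts.values()))
        genome_len = sum(readset.chrom_lengths.values()) or 1
        mean_depth = total_reads * readset.read_length / genome_len
        return cls(window_size, counts, readset.read_length, mean_depth)

    def depth_at(self, chrom: str, pos: int) -> float:
        arr = self.counts.get(chrom)
        if arr is None or arr.size == 0:
            return 0.0
        w = min(pos // self.window_size, arr.size - 1)
        return float(arr[w]) * self.read_length / self.window_size


def filter_high_coverage(
    calls: list[InsertionCall],
    profile: CoverageProfile,
    ratio: float = DEFAULT_COVERAGE_RATIO,
) -> tuple[list[InsertionCall], list[InsertionCall]]:
    """Remove calls whose breakpoint window has depth >= ratio x mean."""
    if profile.mean_depth <= 0:
        raise ValueError("mean depth is zero; coverage filter undefined")
    kept, removed = [], []
    threshold = ratio * profile.mean_depth
    for call in calls:
        if profile.depth_at(call.chrom, call.breakpoint) >= threshold:
            call.filter_flags.append("high_coverage")
            removed.append(call)
        else:
            kept.append(call)
    return kept, removed


def merge_same_position(calls: list[InsertionCall]) -> list[InsertionCall]:
    """Collapse calls at exactly the same (chrom, breakpoint).

    The merged call keeps the transposon with the most supporting reads
    (ties to the lexicographically first name) and absorbs all supporting
    reads; its class is re-derived from the merged sides.
    """
    by_pos: dict[tuple[str, int], list[InsertionCall]] = defaultdict(list)
    for call in calls:
        by_pos[(call.chrom, call.breakpoint)].append(call)
    merged: list[InsertionCall] = []
    for key in sorted(by_pos):
        group = by_pos[key]
        if len(group) == 1:
            merged.append(group[0])
            continue
        group.sort(key=lambda c: (-c.n_support, c.transposon))
        winner = group[0]
        for other in group[1:]:
            winner.reads_left.extend(other.reads_left)
            winner.reads_right.extend(other.reads_right)
            winner.filter_flags.append(f"merged:{other.transposon}")
        if len(winner.reads) == 1:
            winner.insertion_class = "singleton"
        elif winner.reads_left and winner.reads_right:
            winner.insertion_class = "1p1"
        else:
            winner.insertion_class = "2p"
        merged.append(winner)
    return merged


def apply_filters(
    calls: list[InsertionCall],
    annotation: RepeatAnnotation | None = None,
    readset: ReadSet | None = None,
    library: ConsensusLibrary | None = None,
    window_size: int = DEFAULT_WINDOW_SIZE,
    coverage_ratio: float = DEFAULT_COVERAGE_RATIO,
) -> tuple[list[InsertionCall], list[InsertionCall]]:
    """Run the three filters in their canonical order."""
    removed_all: list[InsertionCall] = []
    kept = list(calls)
    if annotation is not None:
        kept, removed, _ = filter_same_transposon(kept, annotation, library)
        removed_all.extend(removed)
    if readset is not None:
        profile = CoverageProfile.from_readset(readset, window_size)
        if profile.mean_depth > 0:
            kept, removed = filter_high_coverage(kept, profile, coverage_ratio)
            removed_all.extend(removed)
    kept = merge_same_position(kept)
    return kept, removed_all
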