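"""Curation of a transposon-insertion benchmark from long-read alignments.

Large insertion events are taken directly from CIGAR insertion
operations (>= 300 bp), validated by aligning the inserted sequence to
the consensus library (the alignment must cover more than half of the
insert and start/end within 500 nt of its two ends), merged within 50 bp,
and kept when more than one read supports them.  Insertion frequency uses
the same S/(S+2R) estimator as the short-read caller: reads split within
50 bp of the breakpoint support the insertion (a read split at both ends
counts twice), reads crossing the breakpoint by at least 50 bp are
reference reads.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .calling import estimate_insertion_frequency
from .consensus import ConsensusAligner
from .io import ConsensusLibrary, RepeatAnnotation

MIN_INSERT_LEN = 300
MERGE_DISTANCE = 50
END_WINDOW = 500  # consensus alignment must start/end within this of the insert ends
SPLIT_WINDOW = 50  # clip/insertion within this of the breakpoint supports it
CROSS_MARGIN = 50  # reference reads must cross the breakpoint by this much
MIN_CLIP_EVIDENCE = 100  # shortest clip counted as split evidence


@dataclass
class LongReadInsertionEvent:
    chrom: str
    position: int  # genomic position of the insertion op
    sequence: str
    read_name: str
    transposon: str | None = None
    te_start: int | None = None
    te_end: int | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CuratedInsertion:
    chrom: str
    breakpoint: int
    transposon: str
    n_supporting: int
    read_names: list[str] = field(default_factory=list)
    te_start: int = 0
    te_end: int = 0
    n_reference: int = 0
    frequency: float = float("nan")
    in_same_transposon_copy: bool = False

    # aliases so benchmark matching works on curated insertions too
    @property
    def pos(self) -> int:
        return self.breakpoint

    @property
    def family(self) -> str:
        return self.transposon

    @property
    def n_support(self) -> int:
        return self.n_supporting


def extract_long_insertions(
    alignments: Iterable[pysam.AlignedSegment] | str | Path,
    min_len: int = MIN_INSERT_LEN,
) -> list[LongReadInsertionEvent]:
    """One event per CIGAR insertion operation of at least ``min_len``."""
    if isinstance(alignments, (str, Path)):
        mode = "rb" if str(alignments).endswith(".bam") else "r"
        fh = pysam.AlignmentFile(str(alignments), mode, check_sq=False)
        records: Iterable[pysam.AlignedSegment] = fh
    else:
        fh = None
        records = alignments
    events: list[LongReadInsertionEvent] = []
    try:
        for rec in records:
            if rec.is_unmapped or rec.is_secondary or rec.cigartuples is None:
                continue
            if rec.query_sequence is None:
                warnings.warn(f"read {rec.query_name!r} lacks a sequence; skipped")
                continue
            ref_pos = rec.reference_start
            q_pos = 0
            for op, n in rec.cigartuples:
                if op == 1:  # I
                    if n >= min_len:
                        events.append(
                            LongReadInsertionEvent(
                                chrom=rec.reference_name,
                                position=ref_pos,
                                sequence=rec.query_sequence[q_pos : q_pos + n],
                                read_name=rec.query_name,
                            )
                        )
                    q_pos += n
                elif op in (0, 7, 8):  # M, =, X
                    ref_pos += n
                    q_pos += n
                elif op in (2, 3):  # D, N
                    ref_pos += n
                elif op == 4:  # S
                    q_pos += n
    finally:
        if fh is not None:
            fh.close()
    return events


def validate_te_insertion(
    event: LongReadInsertionEvent,
    library: ConsensusLibrary | None = None,
    aligner: ConsensusAligner | None = None,
    end_window: int = END_WINDOW,
) -> str | None:
    """Name of the inserted transposon if the event validates, else None.

    The insert must align to a consensus over more than half its length,
    starting within ``end_window`` nt of the insert 5' end and ending
    within ``end_window`` nt of its 3' end.  The matched consensus span
    is recorded on the event.
    """
    if aligner is None:
        if library is None:
            raise ValueError("provide a library or an aligner")
        aligner = ConsensusAligner(library)
    hit = aligner.align(event.sequence)
    if hit is None:
        return None
    aligned_query = hit.q_end - hit.q_start
    if aligned_query * 2 <= event.length:
        return None
    if hit.q_start > end_window:
        return None
    if event.length - hit.q_end > end_window:
        return None
    event.transposon = hit.transposon
    event.te_start = hit.hit_start
    event.te_end = hit.hit_end
    return hit.transposon


def merge_and_filter(
    events: Sequence[LongReadInsertionEvent],
    merge_distance: int = MERGE_DISTANCE,
    min_reads: int = 2,
    annotation: RepeatAnnotation | None = None,
) -> list[CuratedInsertion]:
    """Single-linkage merge of validated events within ``merge_distance``
    per transposon; the breakpoint is the modal event position (ties to
    the smallest); events supported by fewer than ``min_reads`` reads are
    dropped.  If an annotation is given, insertions inside an annotated
    copy of the same transposon are flagged (not removed) for manual
    review."""
    groups: dict[tuple[str, str], list[LongReadInsertionEvent]] = defaultdict(list)
    for ev in events:
        if ev.transposon is None:
            continue
        groups[(ev.chrom, ev.transposon)].append(ev)
    out: list[CuratedInsertion] = []
    for (chrom, te), members in sorted(groups.items()):
        members.sort(key=lambda e: e.position)
        cluster: list[LongReadInsertionEvent] = []
        clusters: list[list[LongReadInsertionEvent]] = []
        for ev in members:
            if cluster and ev.position - cluster[-1].position > merge_distance:
                clusters.append(cluster)
                cluster = []
            cluster.append(ev)
        if cluster:
            clusters.append(cluster)
        for cl in clusters:
            names = sorted({e.read_name for e in cl})
            if len(names) < min_reads:
                continue
            counts = Counter(e.position for e in cl)
            best = max(counts.values())
            breakpoint = min(p for p, n in counts.items() if n == best)
            ins = CuratedInsertion(
                chrom=chrom,
                breakpoint=breakpoint,
                transposon=te,
                n_supporting=len(cl),
                read_names=names,
                te_start=min(e.te_start for e in cl if e.te_start is not None),
                te_end=max(e.te_end for e in cl if e.te_end is not None),
            )
            if annotation is not None:
                ins.in_same_transposon_copy = any(
                    iv.name == te
                    for iv in annotation.overlapping(chrom, breakpoint)
                )
            out.append(ins)
    return out


def longread_frequency(
    insertion: CuratedInsertion,
    alignments: Iterable[pysam.AlignedSegment] | str | Path,
    split_window: int = SPLIT_WINDOW,
    cross_margin: int = CROSS_MARGIN,
    min_insert_len: int = MIN_INSERT_LEN,
) -> float:
    """Frequency of one curated insertion from the long-read alignments.

    Per read overlapping the breakpoint: a retained insertion op within
    ``split_window`` of the breakpoint counts as two supporting reads
    (the read splits at both insertion ends); a soft/hard clip boundary
    within the window counts as one; otherwise a read whose aligned span
    crosses the breakpoint by at least ``cross_margin`` on both sides is
    a reference read.  Sets and returns S/(S+2R)."""
    if isinstance(alignments, (str, Path)):
        mode = "rb" if str(alignments).endswith(".bam") else "r"
        fh = pysam.AlignmentFile(str(alignments), mode, check_sq=False)
        records: Iterable[pysam.AlignedSegment] = fh
    else:
        fh = None
        records = alignments
    bp = insertion.breakpoint
    S = 0
    R = 0
    try:
        for rec in records:
            if rec.is_unmapped or rec.is_secondary or rec.cigartuples is None:
                continue
            if rec.reference_name != insertion.chrom:
                continue
            start, end = rec.reference_start, rec.reference_end
            if not (start - split_window <= bp <= end + split_window):
                continue
            support = 0
            ref_pos = start
            for op, n in rec.cigartuples:
                if op == 1 and n >= min_insert_len:
                    if abs(ref_pos - bp) <= split_window:
                        support = 2  # splits at both insertion ends
                elif op in (0, 2, 3, 7, 8):
                    ref_pos += n
            if support == 0:
                op0, n0 = rec.cigartuples[0]
                op1, n1 = rec.cigartuples[-1]
                if op0 in (4, 5) and n0 >= MIN_CLIP_EVIDENCE and abs(start - bp) <= split_window:
                    support = 1
                elif op1 in (4, 5) and n1 >= MIN_CLIP_EVIDENCE and abs(end - bp) <= split_window:
                    support = 1
            if support:
                S += support
            elif start <= bp - cross_margin and end >= bp + cross_margin:
                R += 1
    finally:
        if fh is not None:
            fh.close()
    insertion.n_reference = R
    insertion.frequency = estimate_insertion_frequency(S, R) if S else 0.0
    return insertion.frequency


def curate_benchmark(
    alignments_path: str | Path,
    library: ConsensusLibrary,
    annotation: RepeatAnnotation | None = None,
    min_insert_len: int = MIN_INSERT_LEN,
    merge_distance: int = MERGE_DISTANCE,
) -> list[CuratedInsertion]:
    """Full long-read curation: extract, validate, merge, quantify."""
    events = extract_long_insertions(alignments_path, min_insert_len)
    aligner = ConsensusAligner(library)
    validated = [
        ev for ev in events if validate_te_insertion(ev, aligner=aligner) is not None
    ]
    curated = merge_and_filter(
        validated, merge_distance=merge_distance, annotation=annotation
    )
    for ins in curated:
        longread_frequency(ins, alignments_path, min_insert_len=min_insert_len)
    return curated
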