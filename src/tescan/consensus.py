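"""Local alignment of candidate reads against the transposon consensus
library.

Scoring is bwa-mem-like (match +1, mismatch -2, gap open -3, gap extend
-1).  For speed, alignment is seeded: a candidate is only aligned against
consensus windows with which it shares at least one exact k-mer (k=13,
either strand), then extended with a Smith-Waterman local alignment
(Biopython's PairwiseAligner).  An exhaustive mode aligning against every
full-length consensus on both strands is available for validation.

A hit is reported only if its identity is at least ``1 - max_divergence``
(default 10% divergence) and it spans at least ``min_aligned`` consensus
bases.  Ties are broken deterministically: higher score, then longer
aligned length, then lexicographically smallest transposon name, then
forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from Bio import Align
from Bio.Seq import Seq

from .io import ConsensusLibrary
from .readpairs import Candidate

DEFAULT_MAX_DIVERGENCE = 0.10
DEFAULT_MIN_ALIGNED = 20
SEED_K = 13
_WINDOW_PAD = 24


@dataclass(frozen=True)
class ConsensusHit:
    """Best local alignment of a candidate sequence to one consensus."""

    transposon: str
    family: str
    hit_start: int  # 0-based half-open, forward consensus coordinates
    hit_end: int
    strand: str  # '+' if the read matches the consensus as given
    aligned_length: int
    identity: float
    score: float
    q_start: int  # query coordinates, original read orientation
    q_end: int


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


class ConsensusAligner:
    """Reusable aligner holding the k-mer index of a consensus library."""

    def __init__(
        self,
        library: ConsensusLibrary,
        match: float = 1.0,
        mismatch: float = -2.0,
        gap_open: float = -3.0,
        gap_extend: float = -1.0,
        max_divergence: float = DEFAULT_MAX_DIVERGENCE,
        min_aligned: int = DEFAULT_MIN_ALIGNED,
        k: int = SEED_K,
    ):
        self.library = library
        self.max_divergence = max_divergence
        self.min_aligned = min_aligned
        self.k = k
        self.names = library.names
        self._seqs = [library.entries[n] for n in self.names]
        self._aligner = Align.PairwiseAligner()
        self._aligner.mode = "local"
        self._aligner.match_score = match
        self._aligner.mismatch_score = mismatch
        self._aligner.open_gap_score = gap_open
        self._aligner.extend_gap_score = gap_extend
        self._index: dict[str, list[tuple[int, int]]] = {}
        for ti, seq in enumerate(self._seqs):
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((ti, pos))

    # -- internals ---------------------------------------------------------

    def _seed_windows(self, query: str) -> dict[tuple[int, str], tuple[int, int]]:
        """Map (te index, strand) -> consensus window implied by shared
        k-mers with the query (given in read orientation)."""
        windows: dict[tuple[int, str], tuple[int, int]] = {}
        k = self.k
        for strand, q in (("+", query), ("-", _revcomp(query))):
            qlen = len(q)
            for qpos in range(qlen - k + 1):
                hits = self._index.get(q[qpos : qpos + k])
                if not hits:
                    continue
                for ti, cpos in hits:
                    diag = cpos - qpos
                    key = (ti, strand)
                    lo, hi = windows.get(key, (diag, diag))
                    windows[key] = (min(lo, diag), max(hi, diag))
        return windows

    def _score_window(
        self, query_oriented: str, ti: int, strand: str, w_start: int, w_end: int
    ) -> ConsensusHit | None:
        cons = self._seqs[ti]
        w_start = max(0, w_start)
        w_end = min(len(cons), w_end)
        if w_end - w_start < self.min_aligned:
            return None
        window = cons[w_start:w_end]
        alignments = self._aligner.align(window, query_oriented)
        try:
            aln = alignments[0]
        except IndexError:
            return None
        counts = aln.counts()
        n_id = counts.identities
        n_cols = counts.identities + counts.mismatches + counts.internal_gaps
        if n_cols == 0:
            return None
        identity = n_id / n_cols
        t_blocks, q_blocks = aln.aligned
        hit_start = w_start + int(t_blocks[0][0])
        hit_end = w_start + int(t_blocks[-1][1])
        q0, q1 = int(q_blocks[0][0]), int(q_blocks[-1][1])
        qlen = len(query_oriented)
        if strand == "-":
            q0, q1 = qlen - q1, qlen - q0
        aligned_length = hit_end - hit_start
        if aligned_length < self.min_aligned:
            return None
        if identity < 1.0 - self.max_divergence:
            return None
        name = self.names[ti]
        return ConsensusHit(
            transposon=name,
            family=self.library.family_of[name],
            hit_start=hit_start,
            hit_end=hit_end,
            strand=strand,
            aligned_length=aligned_length,
            identity=identity,
            score=float(aln.score),
            q_start=q0,
            q_end=q1,
        )

    # -- public API --------------------------------------------------------

    def align(self, seq: str, exhaustive: bool = False) -> ConsensusHit | None:
        """Best consensus hit of ``seq`` (read orientation), or None."""
        seq = seq.upper()
        if len(seq) < self.min_aligned:
            return None
        hits: list[ConsensusHit] = []
        if exhaustive:
            targets = [
                (ti, strand, 0, len(self._seqs[ti]))
                for ti in range(len(self._seqs))
                for strand in ("+", "-")
            ]
        else:
            targets = [
                (ti, strand, lo - _WINDOW_PAD, hi + len(seq) + _WINDOW_PAD)
                for (ti, strand), (lo, hi) in self._seed_windows(seq).items()
            ]
        for ti, strand, w_start, w_end in targets:
            q = seq if strand == "+" else _revcomp(seq)
            hit = self._score_window(q, ti, strand, w_start, w_end)
            if hit is not None:
                hits.append(hit)
        if not hits:
            return None
        hits.sort(
            key=lambda h: (-h.score, -h.aligned_length, h.transposon, h.strand)
        )
        return hits[0]


def align_candidate(
    sequence: str,
    library: ConsensusLibrary,
    max_divergence: float = DEFAULT_MAX_DIVERGENCE,
    min_aligned: int = DEFAULT_MIN_ALIGNED,
    aligner: ConsensusAligner | None = None,
    exhaustive: bool = False,
) -> ConsensusHit | None:
    """One-shot convenience wrapper around :class:`ConsensusAligner`.

    For many candidates, build one ConsensusAligner and reuse it.
    """
    if aligner is None:
        aligner = ConsensusAligner(
            library, max_divergence=max_divergence, min_aligned=min_aligned
        )
    return aligner.align(sequence, exhaustive=exhaustive)


# ---------------------------------------------------------------------------
# Supporting reads
# ---------------------------------------------------------------------------

@dataclass
class SupportingRead:
    """A genome-anchored read whose candidate portion hit a consensus."""

    __slots__ = (
        "qname", "chrom", "anchor_pos", "side", "origin", "hit", "clip_site",
        "is_chimera_truth",
    )

    qname: str
    chrom: str
    anchor_pos: int
    side: str  # 'left' | 'right'
    origin: str  # 'split' | 'unsplit'
    hit: ConsensusHit
    clip_site: int | None
    is_chimera_truth: bool

    @property
    def family(self) -> str:
        return self.hit.family


def assign_supporting_reads(
    candidates: Iterable[Candidate],
    library: ConsensusLibrary | None = None,
    aligner: ConsensusAligner | None = None,
) -> list[SupportingRead]:
    """Align candidates to the consensus library; keep those with a hit."""
    if aligner is None:
        if library is None:
            raise ValueError("provide either a library or an aligner")
        aligner = ConsensusAligner(library)
    out: list[SupportingRead] = []
    for cand in candidates:
        hit = aligner.align(cand.seq)
        if hit is None:
            continue
        out.append(
            SupportingRead(
                qname=cand.qname,
                chrom=cand.chrom,
                anchor_pos=cand.anchor_pos,
                side=cand.side,
                origin="split" if cand.origin == "softclip" else "unsplit",
                hit=hit,
                clip_site=cand.clip_site,
                is_chimera_truth=cand.is_chimera_truth,
            )
        )
    return out
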