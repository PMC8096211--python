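"""Fragment-length model and read-pair classification.

Every template is assigned exactly one class:

``proper``
    both reads uniquely and properly mapped, no informative soft clip;
``discordant_candidate``
    exactly one read uniquely mapped, the mate unmapped or multi-mapped —
    the mate is the candidate for consensus alignment;
``split_candidate``
    a properly mapped pair in which the 5' end of one read is soft-clipped
    by at least ``min_clip`` bases — the clip is the candidate;
``uninformative``
    everything else.

A :class:`ReadSet` keeps the (typically vast) fraction of pairs that are
uniquely mapped without any soft clip in flat numpy arrays, and only the
informative pairs as Python objects, so multi-million-pair libraries fit
in memory and classify in vectorised time.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

from .io import AlignmentRecord, ReadPairRecord, read_alignment_pairs

DEFAULT_MAPQ_UNIQUE = 20
DEFAULT_MIN_CLIP = 10


class PairClass(enum.Enum):
    PROPER = "proper"
    DISCORDANT = "discordant_candidate"
    SPLIT = "split_candidate"
    UNINFORMATIVE = "uninformative"


# ---------------------------------------------------------------------------
# Fragment length model
# ---------------------------------------------------------------------------

class TooFewFragmentsError(RuntimeError):
    pass


@dataclass
class FragmentLengthModel:
    """Empirical fragment-length distribution of the library.

    ``f95`` is the 95th-percentile fragment length, computed from pairs
    that map entirely (no clips) and uniquely to one location; it drives
    both the read clustering distance and the transposon end definition.
    """

    f95: float
    mean: float
    sd: float
    n_pairs_sampled: int

    @classmethod
    def from_lengths(cls, lengths: Sequence[int] | np.ndarray) -> "FragmentLengthModel":
        arr = np.abs(np.asarray(lengths, dtype=np.float64))
        arr = arr[arr > 0]
        if arr.size == 0:
            raise TooFewFragmentsError(
                "no usable template lengths; supply f95 manually"
            )
        return cls(
            f95=float(np.percentile(arr, 95)),
            mean=float(arr.mean()),
            sd=float(arr.std()),
            n_pairs_sampled=int(arr.size),
        )


def _is_unique(read: AlignmentRecord, mapq_unique: int) -> bool:
    return read.mapped and not read.is_secondary and read.mapq >= mapq_unique


def _is_unclipped(read: AlignmentRecord) -> bool:
    return read.clip_left == 0 and read.clip_right == 0


def estimate_fragment_model(
    pairs: Iterable[ReadPairRecord],
    min_pairs: int = 100,
    mapq_unique: int = DEFAULT_MAPQ_UNIQUE,
) -> FragmentLengthModel:
    """Estimate the fragment-length model from properly mapped unique,
    unsplit pairs.

    Template length is |SAM TLEN|; pairs with TLEN 0 are excluded.  With
    fewer than ``min_pairs`` usable pairs an error asks the user to supply
    f95 directly.
    """
    lengths = []
    for pair in pairs:
        r1, r2 = pair.reads
        if not (r1.proper_flag and r2.proper_flag):
            continue
        if not (_is_unique(r1, mapq_unique) and _is_unique(r2, mapq_unique)):
            continue
        if not (_is_unclipped(r1) and _is_unclipped(r2)):
            continue
        if r1.tlen == 0:
            continue
        lengths.append(abs(r1.tlen))
    if len(lengths) < min_pairs:
        raise TooFewFragmentsError(
            f"only {len(lengths)} properly mapped unique unsplit pairs "
            f"(need >= {min_pairs}); supply f95 manually"
        )
    return FragmentLengthModel.from_lengths(np.array(lengths))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class Candidate:
    """A read (or clipped read portion) to be aligned against the
    transposon consensus library, together with its genome anchor."""

    __slots__ = (
        "qname", "chrom", "anchor_pos", "side", "origin", "seq", "clip_site",
        "is_chimera_truth",
    )

    qname: str
    chrom: str
    anchor_pos: int  # anchor 3'-end coordinate (junction-proximal)
    side: str  # 'left' | 'right' of the putative insertion
    origin: str  # 'unmapped' | 'multimapped' | 'softclip'
    seq: str  # candidate sequence in read orientation
    clip_site: int | None  # soft-clip boundary when clip evidence exists
    is_chimera_truth: bool


def classify_pair(
    pair: ReadPairRecord,
    mapq_unique: int = DEFAULT_MAPQ_UNIQUE,
    min_clip: int = DEFAULT_MIN_CLIP,
) -> tuple[PairClass, Candidate | None]:
    """Classify one read pair and extract its candidate, if any."""
    r1, r2 = pair.reads
    u1, u2 = _is_unique(r1, mapq_unique), _is_unique(r2, mapq_unique)

    if u1 and u2:
        if not (r1.proper_flag and r2.proper_flag):
            return PairClass.UNINFORMATIVE, None
        # split candidate: a 5'-clipped read in a proper pair
        clipped = [r for r in (r1, r2) if r.soft_clip_5p >= min_clip]
        if clipped:
            read = max(clipped, key=lambda r: r.soft_clip_5p)
            seq = read.clip_5p_seq()
            if seq is not None:
                if read.strand == "+":
                    # clip on the genome-left of the anchor: the transposon
                    # lies left of the mapped portion, the read sits on the
                    # right side of the junction
                    side, pos = "right", read.pos
                else:
                    side, pos = "left", read.reference_end
                cand = Candidate(
                    qname=read.qname,
                    chrom=read.chrom,
                    anchor_pos=pos,
                    side=side,
                    origin="softclip",
                    seq=seq,
                    clip_site=pos,
                    is_chimera_truth=pair.is_chimera_truth,
                )
                return PairClass.SPLIT, cand
        return PairClass.PROPER, None

    if u1 != u2:
        anchor, other = (r1, r2) if u1 else (r2, r1)
        if other.mapped and other.mapq >= mapq_unique:
            return PairClass.UNINFORMATIVE, None
        seq = other.read_oriented_seq()
        if seq is None:
            return PairClass.UNINFORMATIVE, None
        if anchor.strand == "+":
            side, pos = "left", anchor.reference_end
        else:
            side, pos = "right", anchor.pos
        clip_site = None
        if anchor.strand == "+" and anchor.clip_right >= min_clip:
            clip_site = anchor.reference_end
        elif anchor.strand == "-" and anchor.clip_left >= min_clip:
            clip_site = anchor.pos
        cand = Candidate(
            qname=anchor.qname,
            chrom=anchor.chrom,
            anchor_pos=pos,
            side=side,
            origin="unmapped" if not other.mapped else "multimapped",
            seq=seq,
            clip_site=clip_site,
            is_chimera_truth=pair.is_chimera_truth,
        )
        return PairClass.DISCORDANT, cand

    return PairClass.UNINFORMATIVE, None


def extract_candidates(
    pairs: Iterable[ReadPairRecord],
    mapq_unique: int = DEFAULT_MAPQ_UNIQUE,
    min_clip: int = DEFAULT_MIN_CLIP,
) -> list[Candidate]:
    """Candidates from a stream of pairs: one per discordant/split pair."""
    out = []
    for pair in pairs:
        _, cand = classify_pair(pair, mapq_unique, min_clip)
        if cand is not None:
            out.append(cand)
    return out


# ---------------------------------------------------------------------------
# ReadSet
# ---------------------------------------------------------------------------

@dataclass
class BulkPairs:
    """Flat arrays for pairs that are uniquely mapped without soft clips.

    Such pairs can only classify as ``proper`` (proper flag set) or
    ``uninformative`` (both-unique discordant), so nothing but coordinates
    needs to be retained.
    """

    chrom_id: np.ndarray  # int32, index into ReadSet.chroms
    start1: np.ndarray  # leftmost read start
    end1: np.ndarray
    start2: np.ndarray
    end2: np.ndarray
    tlen: np.ndarray  # |template length|, 0 when unknown
    proper: np.ndarray  # bool

    def __len__(self) -> int:
        return int(self.chrom_id.size)

    @property
    def frag_start(self) -> np.ndarray:
        return np.minimum(self.start1, self.start2)

    @property
    def frag_end(self) -> np.ndarray:
        return np.maximum(self.end1, self.end2)

    @classmethod
    def empty(cls) -> "BulkPairs":
        z = np.zeros(0, dtype=np.int64)
        return cls(z.astype(np.int32), z, z, z, z, z, z.astype(bool))


class ReadSet:
    """A whole sequencing library, split into bulk arrays + featured pairs.

    ``featured`` holds every pair that could be a candidate (discordant,
    clipped, low-MAPQ or partially unmapped); ``unanchored`` holds pairs
    with both reads unmapped, which carry no genome anchor but still map
    to consensus sequences (used for chimera normalisation).
    """

    def __init__(
        self,
        chroms: Sequence[str],
        chrom_lengths: dict[str, int],
        bulk: BulkPairs,
        featured: list[ReadPairRecord],
        unanchored: Callable[[], Iterator[ReadPairRecord]] | None = None,
        read_length: int = 100,
    ):
        self.chroms = list(chroms)
        self.chrom_lengths = dict(chrom_lengths)
        self.bulk = bulk
        self.featured = featured
        self._unanchored = unanchored or (lambda: iter(()))
        self.read_length = read_length

    def iter_unanchored(self) -> Iterator[ReadPairRecord]:
        return self._unanchored()

    @property
    def n_pairs(self) -> int:
        return len(self.bulk) + len(self.featured)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[ReadPairRecord],
        chrom_lengths: dict[str, int],
        mapq_unique: int = DEFAULT_MAPQ_UNIQUE,
        read_length: int = 100,
    ) -> "ReadSet":
        chroms = list(chrom_lengths)
        chrom_idx = {c: i for i, c in enumerate(chroms)}
        cols: list[list[int]] = [[] for _ in range(7)]
        featured: list[ReadPairRecord] = []
        unanchored: list[ReadPairRecord] = []
        for pair in pairs:
            r1, r2 = pair.reads
            if (
                _is_unique(r1, mapq_unique)
                and _is_unique(r2, mapq_unique)
                and _is_unclipped(r1)
                and _is_unclipped(r2)
                and not pair.secondary
            ):
                cid = chrom_idx.get(r1.chrom)
                if cid is None:
                    cid = len(chroms)
                    chrom_idx[r1.chrom] = cid
                    chroms.append(r1.chrom)
                cols[0].append(cid)
                cols[1].append(r1.pos)
                cols[2].append(r1.reference_end)
                cols[3].append(r2.pos)
                cols[4].append(r2.reference_end)
                proper = (
                    r1.proper_flag and r2.proper_flag and r1.chrom == r2.chrom
                )
                cols[5].append(abs(r1.tlen) if proper else 0)
                cols[6].append(1 if proper else 0)
            elif not r1.mapped and not r2.mapped:
                unanchored.append(pair)
            else:
                featured.append(pair)
        bulk = BulkPairs(
            chrom_id=np.array(cols[0], dtype=np.int32),
            start1=np.array(cols[1], dtype=np.int64),
            end1=np.array(cols[2], dtype=np.int64),
            start2=np.array(cols[3], dtype=np.int64),
            end2=np.array(cols[4], dtype=np.int64),
            tlen=np.array(cols[5], dtype=np.int64),
            proper=np.array(cols[6], dtype=bool),
        )
        return cls(
            chroms,
            chrom_lengths,
            bulk,
            featured,
            unanchored=(lambda: iter(unanchored)),
            read_length=read_length,
        )

    @classmethod
    def from_sam(
        cls,
        path: str | Path,
        mapq_unique: int = DEFAULT_MAPQ_UNIQUE,
        read_length: int = 100,
    ) -> "ReadSet":
        import pysam

        mode = "rb" if str(path).endswith(".bam") else "r"
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
            chrom_lengths = dict(zip(fh.references, fh.lengths))
        return cls.from_pairs(
            read_alignment_pairs(path),
            chrom_lengths,
            mapq_unique=mapq_unique,
            read_length=read_length,
        )

    # -- derived quantities ------------------------------------------------

    def fragment_model(self, min_pairs: int = 100) -> FragmentLengthModel:
        tl = self.bulk.tlen[self.bulk.proper & (self.bulk.tlen > 0)]
        extra = []
        for pair in self.featured:
            r1, r2 = pair.reads
            if (
                r1.proper_flag
                and r2.proper_flag
                and _is_unique(r1, DEFAULT_MAPQ_UNIQUE)
                and _is_unique(r2, DEFAULT_MAPQ_UNIQUE)
                and _is_unclipped(r1)
                and _is_unclipped(r2)
                and r1.tlen != 0
            ):
                extra.append(abs(r1.tlen))
        lengths = np.concatenate([tl, np.array(extra, dtype=np.int64)])
        if lengths.size < min_pairs:
            raise TooFewFragmentsError(
                f"only {lengths.size} usable pairs (need >= {min_pairs}); "
                "supply f95 manually"
            )
        return FragmentLengthModel.from_lengths(lengths)

    def candidates(
        self,
        mapq_unique: int = DEFAULT_MAPQ_UNIQUE,
        min_clip: int = DEFAULT_MIN_CLIP,
    ) -> list[Candidate]:
        return extract_candidates(self.featured, mapq_unique, min_clip)
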