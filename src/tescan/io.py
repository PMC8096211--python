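"""Readers and writers for the external formats the pipeline touches.

All in-memory coordinates are 0-based, half-open.  Conversions from 1-based
conventions (SAM POS, RepeatMasker .out) happen here and only here.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import pysam
from Bio import SeqIO
from Bio.Seq import Seq


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open a text file, transparently decompressing ``.gz``."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class GenomeSequence:
    """One reference sequence (chromosome or contig)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ParseError(
                f"sequence {self.name!r} contains non-ACGTN characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (possibly gzipped) FASTA file into uppercase sequences.

    Ambiguity codes other than N are rejected; an empty file yields an
    empty list.
    """
    records = []
    with open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            if not seq:
                raise ParseError(f"FASTA record {rec.id!r} has an empty sequence")
            records.append(GenomeSequence(rec.id, seq))
    return records


@dataclass
class ConsensusLibrary:
    """Transposon consensus sequences with an optional family grouping.

    Without a grouping table every consensus is its own family.
    """

    entries: dict[str, str]
    family_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.entries.items():
            if not seq:
                raise ParseError(f"consensus {name!r} has an empty sequence")
        for name in self.entries:
            self.family_of.setdefault(name, name)

    @property
    def length_of(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.entries.items()}

    @property
    def names(self) -> list[str]:
        return sorted(self.entries)

    def families(self) -> list[str]:
        return sorted(set(self.family_of[n] for n in self.entries))

    def members(self, family: str) -> list[str]:
        return sorted(n for n in self.entries if self.family_of[n] == family)

    @classmethod
    def from_fasta(
        cls, path: str | Path, family_table: str | Path | None = None
    ) -> "ConsensusLibrary":
        entries = {rec.name: rec.sequence for rec in read_fasta(path)}
        family_of: dict[str, str] = {}
        if family_table is not None:
            with open_text(family_table) as fh:
                for i, line in enumerate(fh, 1):
                    line = line.rstrip("\n")
                    if not line or line.startswith("#"):
                        continue
                    fields = line.split("\t")
                    if len(fields) < 2:
                        raise ParseError(
                            f"{family_table}:{i}: expected two tab-separated columns"
                        )
                    family_of[fields[0]] = fields[1]
        return cls(entries, family_of)


# ---------------------------------------------------------------------------
# Repeat annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    name: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ParseError(
                f"repeat interval {self.chrom}:{self.start}-{self.end} has end <= start"
            )


@dataclass
class RepeatAnnotation:
    """Known transposon copies in the reference genome."""

    intervals: list[RepeatInterval] = field(default_factory=list)

    def overlapping(self, chrom: str, pos: int) -> list[RepeatInterval]:
        return [
            iv
            for iv in self.intervals
            if iv.chrom == chrom and iv.start <= pos < iv.end
        ]


def read_repeat_annotation(path: str | Path, dialect: str = "bed6") -> RepeatAnnotation:
    """Read repeat intervals from BED6 or a RepeatMasker ``.out`` file.

    BED is already 0-based half-open; RepeatMasker begin/end are 1-based
    inclusive and converted here.
    """
    dialect = dialect.lower()
    if dialect not in ("bed6", "repeatmasker_out"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    intervals: list[RepeatInterval] = []
    with open_text(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if dialect == "bed6":
                if line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ParseError(f"{path}:{i}: BED6 needs >= 4 columns")
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{i}: non-numeric coordinates") from exc
                strand = fields[5] if len(fields) > 5 else "+"
                intervals.append(RepeatInterval(fields[0], start, end, fields[3], strand))
            else:
                fields = line.split()
                # header lines of .out start with "SW" / "score" or are blank
                if not fields or not fields[0].isdigit():
                    continue
                if len(fields) < 10:
                    raise ParseError(f"{path}:{i}: truncated RepeatMasker row")
                chrom = fields[4]
                try:
                    begin, end = int(fields[5]), int(fields[6])
                except ValueError as exc:
                    raise ParseError(f"{path}:{i}: non-numeric coordinates") from exc
                strand = "-" if fields[8] in ("C", "-") else "+"
                intervals.append(RepeatInterval(chrom, begin - 1, end, fields[9], strand))
    return RepeatAnnotation(intervals)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class AlignmentRecord:
    """One read of a pair, in 0-based coordinates.

    ``soft_clip_5p``/``soft_clip_3p`` are in *read orientation*: for a
    minus-strand read the 5' clip is the trailing S operation of the
    reference-orientation CIGAR.
    """

    __slots__ = (
        "qname", "read_index", "mapped", "chrom", "pos", "strand", "mapq",
        "cigar", "seq", "is_secondary", "is_supplementary", "mate_chrom",
        "mate_pos", "mate_mapped", "proper_flag", "tlen",
    )

    qname: str
    read_index: int
    mapped: bool
    chrom: str | None
    pos: int
    strand: str
    mapq: int
    cigar: list[tuple[str, int]]
    seq: str | None
    is_secondary: bool
    is_supplementary: bool
    mate_chrom: str | None
    mate_pos: int
    mate_mapped: bool
    proper_flag: bool
    tlen: int

    @property
    def reference_end(self) -> int:
        """0-based exclusive end of the mapped portion."""
        span = sum(n for op, n in self.cigar if op in "MDN=X")
        return self.pos + span

    @property
    def clip_left(self) -> int:
        """Soft clip on the reference-left side."""
        if not self.cigar:
            return 0
        op, n = self.cigar[0]
        return n if op == "S" else 0

    @property
    def clip_right(self) -> int:
        if not self.cigar:
            return 0
        op, n = self.cigar[-1]
        return n if op == "S" else 0

    @property
    def soft_clip_5p(self) -> int:
        return self.clip_left if self.strand == "+" else self.clip_right

    @property
    def soft_clip_3p(self) -> int:
        return self.clip_right if self.strand == "+" else self.clip_left

    def clip_5p_seq(self) -> str | None:
        """Sequence of the 5' soft-clipped portion, in read orientation."""
        n = self.soft_clip_5p
        if n == 0 or self.seq is None:
            return None
        if self.strand == "+":
            return self.seq[:n]
        # stored seq is reference orientation; read 5' end is the
        # reference-right end, read orientation = reverse complement
        return str(Seq(self.seq[-n:]).reverse_complement())

    def read_oriented_seq(self) -> str | None:
        """Full sequence in sequencer (read) orientation."""
        if self.seq is None:
            return None
        if self.strand == "+" or not self.mapped:
            return self.seq
        return str(Seq(self.seq).reverse_complement())


@dataclass
class ReadPairRecord:
    """The two primary alignment records of one template."""

    __slots__ = ("r1", "r2", "secondary", "is_chimera_truth")

    r1: AlignmentRecord
    r2: AlignmentRecord
    secondary: list[AlignmentRecord]
    is_chimera_truth: bool

    def __init__(self, r1, r2, secondary=None, is_chimera_truth=False):
        self.r1 = r1
        self.r2 = r2
        self.secondary = secondary or []
        self.is_chimera_truth = is_chimera_truth

    @property
    def reads(self) -> tuple[AlignmentRecord, AlignmentRecord]:
        return (self.r1, self.r2)


_CIGAR_OPS = "MIDNSHP=X"


def _from_pysam(rec: pysam.AlignedSegment) -> AlignmentRecord:
    cigar = (
        [(_CIGAR_OPS[op], n) for op, n in rec.cigartuples] if rec.cigartuples else []
    )
    mapped = not rec.is_unmapped
    strand = "-" if (mapped and rec.is_reverse) else "+"
    return AlignmentRecord(
        qname=rec.query_name,
        read_index=1 if rec.is_read1 else 2,
        mapped=mapped,
        chrom=rec.reference_name if mapped else None,
        pos=rec.reference_start if mapped else -1,
        strand=strand,
        mapq=rec.mapping_quality,
        cigar=cigar,
        seq=rec.query_sequence,
        is_secondary=rec.is_secondary,
        is_supplementary=rec.is_supplementary,
        mate_chrom=rec.next_reference_name if not rec.mate_is_unmapped else None,
        mate_pos=rec.next_reference_start,
        mate_mapped=not rec.mate_is_unmapped,
        proper_flag=rec.is_proper_pair,
        tlen=rec.template_length,
    )


def read_alignment_pairs(path: str | Path) -> Iterator[ReadPairRecord]:
    """Stream read pairs from a SAM/BAM file, pairing primaries by name.

    Secondary/supplementary records are attached to the pair as evidence.
    Templates with a number of primary records other than two are skipped
    with a warning.  The file does not need to be name-sorted; records are
    buffered until their mate arrives.
    """
    pending: dict[str, list[AlignmentRecord]] = {}
    secondaries: dict[str, list[AlignmentRecord]] = {}
    completed: dict[str, ReadPairRecord] = {}
    last_q: str | None = None

    def _flush(qname: str) -> ReadPairRecord | None:
        pair = completed.pop(qname, None)
        if pair is not None:
            pair.secondary.extend(secondaries.pop(qname, []))
        return pair

    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            a = _from_pysam(rec)
            # emit a completed template once its name block ends, so that
            # trailing secondary records still get attached
            if last_q is not None and a.qname != last_q:
                pair = _flush(last_q)
                if pair is not None:
                    yield pair
            last_q = a.qname
            if a.is_secondary or a.is_supplementary:
                secondaries.setdefault(a.qname, []).append(a)
                continue
            bucket = pending.setdefault(a.qname, [])
            bucket.append(a)
            if len(bucket) == 2:
                del pending[a.qname]
                r1, r2 = sorted(bucket, key=lambda r: r.read_index)
                completed[a.qname] = ReadPairRecord(r1, r2)
    for qname in list(completed):
        pair = _flush(qname)
        if pair is not None:
            yield pair
    for qname, bucket in pending.items():
        warnings.warn(
            f"template {qname!r} has {len(bucket)} primary record(s); skipped"
        )


# ---------------------------------------------------------------------------
# Insertion table
# ---------------------------------------------------------------------------

INSERTION_TABLE_COLUMNS = [
    "chrom", "start", "end", "transposon_strand", "class",
    "n_support_5p", "n_support_3p", "n_reference", "frequency",
    "te_start", "te_end",
]


def write_insertion_table(calls: Iterable, path: str | Path) -> None:
    """Write finalized insertion calls as a deterministic TSV.

    Rows are sorted by (chrom, start, transposon); frequency is printed
    with six decimals.
    """
    rows = sorted(calls, key=lambda c: (c.chrom, c.breakpoint, c.transposon))
    with open_text(path, "wt") as fh:
        fh.write("#" + "\t".join(INSERTION_TABLE_COLUMNS) + "\n")
        for c in rows:
            fh.write(
                "\t".join(
                    [
                        c.chrom,
                        str(c.breakpoint),
                        str(c.breakpoint + 1),
                        f"{c.transposon}:{c.strand}",
                        c.insertion_class,
                        str(c.n_support_5p),
                        str(c.n_support_3p),
                        str(c.n_reference),
                        f"{c.frequency:.6f}",
                        str(c.te_start),
                        str(c.te_end),
                    ]
                )
                + "\n"
            )


def read_insertion_table(path: str | Path) -> list[dict]:
    """Parse a table written by :func:`write_insertion_table`."""
    out = []
    with open_text(path) as fh:
        header = fh.readline().lstrip("#").rstrip("\n").split("\t")
        if header != INSERTION_TABLE_COLUMNS:
            raise ParseError(f"unexpected insertion table header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            te, strand = f[3].rsplit(":", 1)
            out.append(
                {
                    "chrom": f[0],
                    "breakpoint": int(f[1]),
                    "transposon": te,
                    "strand": strand,
                    "insertion_class": f[4],
                    "n_support_5p": int(f[5]),
                    "n_support_3p": int(f[6]),
                    "n_reference": int(f[7]),
                    "frequency": float(f[8]),
                    "te_start": int(f[9]),
                    "te_end": int(f[10]),
                }
            )
    return out
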