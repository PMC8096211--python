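"""Population simulator: genomes with germline and somatic transposon
insertions, paired-end reads, chimeric pairs, and truth records.

The simulated experiment mirrors a pooled sequencing design: a population
of ``n_genomes`` genomes in which each germline insertion sits at the
same coordinate in a fixed fraction of genomes (frequencies 0.25 / 0.5 /
0.75 / 1 by default) and each somatic insertion occurs at its own
coordinate in a single genome.  Reads are 100-nt pairs from ~450 +- 10 nt
fragments with a uniform substitution error rate, and a configurable
fraction of pairs is replaced by chimeras joining two unrelated reads.

Instead of writing FASTQ and invoking an external aligner, the simulator
emits truth alignments directly: read pairs carry their correct genome
coordinates, soft clips at insertion junctions, and unmapped flags for
transposon-interior reads.  The pooled library is generated as a mixture:
genome-wide reference fragments (thinned at each germline breakpoint by
the carrier frequency) plus junction/interior fragments drawn per
insertion event from a locally reconstructed carrier haplotype — this is
exact for the read classes the caller consumes and avoids materialising
10,000 genome copies.  Reference pairs are kept in flat arrays; only
pairs that touch a transposon (or a chimera) become full records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io import AlignmentRecord, ConsensusLibrary, GenomeSequence, ReadPairRecord
from .readpairs import BulkPairs, ReadSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _random_dna(rng: np.random.Generator, length: int, gc: float = 0.45) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def random_genome(
    length: int,
    seed: int | np.random.Generator = 0,
    name: str = "chr1",
    gc: float = 0.42,
) -> GenomeSequence:
    """A synthetic reference chromosome of uniform random sequence."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return GenomeSequence(name, _random_dna(rng, length, gc))


def synthetic_library(
    n_entries: int = 48,
    length_range: tuple[int, int] = (1500, 7500),
    seed: int | np.random.Generator = 0,
    gc: float = 0.45,
    at_rich_tail: Sequence[str] = (),
    tail_length: int = 40,
) -> ConsensusLibrary:
    """A synthetic transposon consensus library.

    Entry names are TE001..TEnnn.  Entries listed in ``at_rich_tail`` get
    an AT-rich final ``tail_length`` nt (mimicking LINE poly-A tails) for
    terminal-composition QC experiments.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    entries = {}
    for i in range(n_entries):
        name = f"TE{i + 1:03d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = _random_dna(rng, length, gc)
        if name in at_rich_tail:
            seq = seq[:-tail_length] + _random_dna(rng, tail_length, gc=0.0)
        entries[name] = seq
    return ConsensusLibrary(entries)


# ---------------------------------------------------------------------------
# Configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class ReadSimParams:
    read_length: int = 100
    frag_mean: float = 450.0
    frag_sd: float = 10.0
    error_rate: float = 0.001
    min_anchor: int = 20  # shortest genome anchor that still maps

    @property
    def frag_max(self) -> int:
        return int(self.frag_mean + 8 * self.frag_sd)


@dataclass
class GermlineSpec:
    n_insertions: int = 400
    frequencies: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)
    partial_fraction: float = 0.10
    min_spacing: int = 3000
    min_insert_length: int = 1200
    partial_fraction_range: tuple[float, float] = (0.3, 0.8)


@dataclass
class SomaticFamilySpec:
    transposon: str
    per_genome_count: int
    partial: bool = False


@dataclass
class SimulationConfig:
    n_genomes: int = 10_000
    depth: float = 20.0
    germline: GermlineSpec | None = None
    somatic: list[SomaticFamilySpec] = field(default_factory=list)
    chimera_rate: float = 0.0
    read: ReadSimParams = field(default_factory=ReadSimParams)
    tsd_length: int = 0
    end_bias: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.chimera_rate < 1:
            raise ValueError("chimera_rate must be in [0, 1)")
        if self.germline is not None:
            for f in self.germline.frequencies:
                if not 0 < f <= 1:
                    raise ValueError("germline frequencies must be in (0, 1]")


@dataclass(frozen=True)
class TruthRecord:
    kind: str  # 'germline' | 'somatic'
    chrom: str
    pos: int  # reference breakpoint, 0-based
    transposon: str
    strand: str
    te_start: int
    te_end: int
    frequency: float  # carrier fraction (1/n_genomes for somatic)
    genome_id: int = -1  # somatic only

    @property
    def insert_length(self) -> int:
        return self.te_end - self.te_start


@dataclass
class Population:
    genome: list[GenomeSequence]
    library: ConsensusLibrary
    config: SimulationConfig
    germline: list[TruthRecord]
    somatic: list[TruthRecord]

    def somatic_counts_per_genome(self) -> dict[str, float]:
        """Simulated de novo insertions per genome for every family."""
        counts = {fam: 0.0 for fam in self.library.families()}
        for spec in self.config.somatic:
            fam = self.library.family_of[spec.transposon]
            counts[fam] += spec.per_genome_count
        return counts


# ---------------------------------------------------------------------------
# Population construction
# ---------------------------------------------------------------------------

def _spaced_positions(
    rng: np.random.Generator, n: int, lo: int, hi: int, min_gap: int
) -> np.ndarray:
    """n sorted positions in [lo, hi) with pairwise gaps >= min_gap."""
    usable = (hi - lo) - (n - 1) * min_gap
    if usable <= n:
        raise ValueError(
            f"interval of {hi - lo} bp cannot hold {n} insertions "
            f"spaced {min_gap} bp apart"
        )
    u = np.sort(rng.integers(0, usable, size=n))
    return lo + u + np.arange(n) * min_gap


def _pick_te_slice(
    rng: np.random.Generator,
    library: ConsensusLibrary,
    te: str,
    partial: bool,
    spec_min_len: int,
    frac_range: tuple[float, float],
) -> tuple[int, int]:
    length = len(library.entries[te])
    if not partial:
        return 0, length
    lo = max(spec_min_len, int(length * frac_range[0]))
    hi = max(lo + 1, int(length * frac_range[1]))
    plen = int(rng.integers(lo, min(hi, length) + 1))
    if plen >= length:
        return 0, length
    start = int(rng.integers(0, length - plen + 1))
    return start, start + plen


def build_population(
    genome: Sequence[GenomeSequence],
    library: ConsensusLibrary,
    config: SimulationConfig,
    seed: int | np.random.Generator = 0,
) -> Population:
    """Place germline and somatic insertions on the reference."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genome = list(genome)
    margin = config.read.frag_max + config.read.read_length + 16
    lengths = np.array([g.length for g in genome], dtype=np.float64)

    germline: list[TruthRecord] = []
    if config.germline is not None:
        g = config.germline
        per_chrom = rng.multinomial(g.n_insertions, lengths / lengths.sum())
        positions: list[tuple[str, int]] = []
        for gi, n_c in enumerate(per_chrom):
            if n_c == 0:
                continue
            pos = _spaced_positions(
                rng, int(n_c), margin, genome[gi].length - margin, g.min_spacing
            )
            positions.extend((genome[gi].name, int(p)) for p in pos)
        n = len(positions)
        n_partial = int(round(g.partial_fraction * n))
        partial_mask = np.zeros(n, dtype=bool)
        partial_mask[rng.choice(n, size=n_partial, replace=False)] = True
        freqs = np.array(g.frequencies)[np.arange(n) % len(g.frequencies)]
        freqs = rng.permuted(freqs)
        te_names = [str(t) for t in rng.choice(library.names, size=n)]
        strands = np.where(rng.integers(0, 2, size=n) == 0, "+", "-")
        for i, (chrom, pos) in enumerate(positions):
            ts, te_end = _pick_te_slice(
                rng, library, te_names[i], bool(partial_mask[i]),
                g.min_insert_length, g.partial_fraction_range,
            )
            germline.append(
                TruthRecord(
                    kind="germline", chrom=chrom, pos=pos, transposon=te_names[i],
                    strand=str(strands[i]), te_start=ts, te_end=te_end,
                    frequency=float(freqs[i]),
                )
            )

    somatic: list[TruthRecord] = []
    for spec in config.somatic:
        total = spec.per_genome_count * config.n_genomes
        chrom_idx = rng.choice(len(genome), size=total, p=lengths / lengths.sum())
        # a partial somatic family transposes as one fixed 5'-truncated
        # fragment (like 5'-truncated L1 copies), shared by all its events
        te_len = len(library.entries[spec.transposon])
        if spec.partial:
            lo = int(0.25 * te_len)
            hi = max(lo + 1, min(int(0.6 * te_len), te_len - 1200))
            ts_fixed = int(rng.integers(lo, hi)) if hi > lo else 0
            slice_fixed = (ts_fixed, te_len)
        else:
            slice_fixed = (0, te_len)
        for j in range(total):
            gi = int(chrom_idx[j])
            pos = int(rng.integers(margin, genome[gi].length - margin))
            ts, te_end = slice_fixed
            somatic.append(
                TruthRecord(
                    kind="somatic", chrom=genome[gi].name, pos=pos,
                    transposon=spec.transposon,
                    strand="+" if rng.integers(0, 2) == 0 else "-",
                    te_start=ts, te_end=te_end,
                    frequency=1.0 / config.n_genomes,
                    genome_id=j % config.n_genomes,
                )
            )
    return Population(genome, library, config, germline, somatic)


# ---------------------------------------------------------------------------
# Read construction around one insertion event
# ---------------------------------------------------------------------------

@dataclass
class _EventContext:
    chrom: str
    b: int  # reference breakpoint
    H: str  # local haplotype: left flank + insert + right flank
    pad: int  # local coordinate of the transposon start
    LI: int  # inserted length
    tsd: int


def _build_event_context(
    flank_left: str, flank_right: str, insert: str, chrom: str, b: int, tsd: int
) -> _EventContext:
    return _EventContext(
        chrom=chrom, b=b, H=flank_left + insert + flank_right,
        pad=len(flank_left), LI=len(insert), tsd=tsd,
    )


def _apply_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    k = rng.binomial(len(seq), error_rate)
    if k == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = rng.integers(0, len(seq), size=k)
    shift = rng.integers(1, 4, size=k)
    lut = {65: 0, 67: 1, 71: 2, 84: 3, 78: 0}
    for i, s in zip(idx, shift):
        arr[i] = _BASES[(lut.get(int(arr[i]), 0) + int(s)) % 4]
    return arr.tobytes().decode()


def _map_event_read(
    ctx: _EventContext,
    u: int,
    v: int,
    seq_ref_orient: str,
    is_reverse: bool,
    min_anchor: int,
    qname: str,
    read_index: int,
) -> AlignmentRecord:
    """Truth alignment of a read covering local haplotype [u, v)."""
    a, c = ctx.pad, ctx.pad + ctx.LI
    left_len = max(0, min(v, a) - u)
    te_len = max(0, min(v, c) - max(u, a))
    right_len = max(0, v - max(u, c))
    length = v - u
    mapped = False
    pos = -1
    cigar: list[tuple[str, int]] = []
    if te_len == 0 and right_len == 0:
        mapped, pos, cigar = True, ctx.b - (a - u), [("M", length)]
    elif te_len == 0 and left_len == 0:
        mapped, pos, cigar = True, ctx.b - ctx.tsd + (u - c), [("M", length)]
    elif left_len > 0 and right_len == 0 and left_len >= min_anchor:
        mapped, pos = True, ctx.b - left_len
        cigar = [("M", left_len), ("S", te_len)]
    elif right_len > 0 and left_len == 0 and right_len >= min_anchor:
        mapped, pos = True, ctx.b - ctx.tsd
        cigar = [("S", te_len), ("M", right_len)]
    seq = seq_ref_orient if (mapped or not is_reverse) else _revcomp(seq_ref_orient)
    return AlignmentRecord(
        qname=qname,
        read_index=read_index,
        mapped=mapped,
        chrom=ctx.chrom if mapped else None,
        pos=pos if mapped else -1,
        strand="-" if (mapped and is_reverse) else "+",
        mapq=60 if mapped else 0,
        cigar=cigar,
        seq=seq,
        is_secondary=False,
        is_supplementary=False,
        mate_chrom=None,
        mate_pos=-1,
        mate_mapped=False,
        proper_flag=False,
        tlen=0,
    )


def _finalise_pair(r1: AlignmentRecord, r2: AlignmentRecord) -> ReadPairRecord:
    for rec, mate in ((r1, r2), (r2, r1)):
        rec.mate_chrom = mate.chrom
        rec.mate_pos = mate.pos
        rec.mate_mapped = mate.mapped
    proper = (
        r1.mapped and r2.mapped and r1.chrom == r2.chrom and r1.strand != r2.strand
    )
    r1.proper_flag = r2.proper_flag = proper
    if proper:
        lo = min(r1.pos, r2.pos)
        hi = max(r1.reference_end, r2.reference_end)
        span = hi - lo
        if r1.pos <= r2.pos:
            r1.tlen, r2.tlen = span, -span
        else:
            r1.tlen, r2.tlen = -span, span
    return ReadPairRecord(r1, r2)


def _event_fragment_pair(
    ctx: _EventContext,
    h: int,
    frag_len: int,
    params: ReadSimParams,
    rng: np.random.Generator,
    qname: str,
) -> ReadPairRecord:
    """One read pair from a fragment starting ``h`` bp left of the
    transposon start on the carrier haplotype."""
    s = ctx.pad + h
    ell = params.read_length
    slice_a = ctx.H[s : s + ell]
    slice_b = ctx.H[s + frag_len - ell : s + frag_len]
    seq_a = _apply_errors(slice_a, rng, params.error_rate)
    seq_b = _apply_errors(slice_b, rng, params.error_rate)
    swap = rng.integers(0, 2) == 1  # which physical read is read1
    ra = _map_event_read(
        ctx, s, s + ell, seq_a, False, params.min_anchor, qname, 2 if swap else 1
    )
    rb = _map_event_read(
        ctx, s + frag_len - ell, s + frag_len, seq_b, True, params.min_anchor,
        qname, 1 if swap else 2,
    )
    r1, r2 = (rb, ra) if swap else (ra, rb)
    return _finalise_pair(r1, r2)


# ---------------------------------------------------------------------------
# Whole-library simulation
# ---------------------------------------------------------------------------

def _oriented_insert(library: ConsensusLibrary, rec: TruthRecord) -> str:
    seq = library.entries[rec.transposon][rec.te_start : rec.te_end]
    return seq if rec.strand == "+" else _revcomp(seq)


def _junction_kind(h: int, frag_len: int, LI: int) -> str | None:
    """Which insertion junction a fragment [h, h+F) (transposon-start
    relative) straddles: 'left', 'right' or None (interior)."""
    if h < 0 < h + frag_len:
        return "left"
    if h < LI < h + frag_len:
        return "right"
    return None


def simulate_read_pairs(
    population: Population,
    seed: int | np.random.Generator = 0,
    emit_reference: bool = True,
) -> ReadSet:
    """Simulate the pooled paired-end library for a population.

    Returns a :class:`ReadSet`: reference-only pairs in bulk arrays,
    transposon-touching and chimeric pairs as full records.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    config = population.config
    params = config.read
    ell = params.read_length
    rate_per_bp = config.depth / (2 * ell)

    chroms = [g.name for g in population.genome]
    chrom_lengths = {g.name: g.length for g in population.genome}
    chrom_seq = {g.name: g.sequence for g in population.genome}
    chrom_index = {name: i for i, name in enumerate(chroms)}

    # --- bulk reference fragments per chromosome -------------------------
    bulk_parts = []
    if emit_reference:
        bp_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        tmp: dict[str, list[tuple[int, float]]] = {}
        for rec in population.germline:
            tmp.setdefault(rec.chrom, []).append((rec.pos, rec.frequency))
        for chrom, items in tmp.items():
            items.sort()
            bp_by_chrom[chrom] = (
                np.array([p for p, _ in items], dtype=np.int64),
                np.array([f for _, f in items]),
            )
        for g in population.genome:
            n = rng.poisson(rate_per_bp * g.length)
            frag = np.clip(
                np.rint(rng.normal(params.frag_mean, params.frag_sd, n)),
                2 * ell, None,
            ).astype(np.int64)
            start = rng.integers(0, g.length - params.frag_max, size=n)
            if g.name in bp_by_chrom:
                bps, freqs = bp_by_chrom[g.name]
                idx = np.searchsorted(bps, start, side="left")
                idx_c = np.clip(idx, 0, len(bps) - 1)
                spans = (idx < len(bps)) & (bps[idx_c] > start) & (
                    bps[idx_c] < start + frag
                )
                drop = spans & (rng.random(n) < freqs[idx_c])
                start, frag = start[~drop], frag[~drop]
                n = start.size
            ci = chrom_index[g.name]
            bulk_parts.append(
                (
                    np.full(n, ci, dtype=np.int32),
                    start,
                    start + ell,
                    start + frag - ell,
                    start + frag,
                    frag,
                )
            )

    # --- insertion-event fragments ---------------------------------------
    featured: list[ReadPairRecord] = []
    unanchored: list[ReadPairRecord] = []
    pad = params.frag_max + 16

    def handle_event(rec: TruthRecord, n_frags: int, ev_id: str) -> None:
        if n_frags == 0:
            return
        insert = _oriented_insert(population.library, rec)
        LI = len(insert)
        seq = chrom_seq[rec.chrom]
        left = seq[rec.pos - pad : rec.pos]
        right = seq[rec.pos - config.tsd_length : rec.pos - config.tsd_length + pad]
        ctx = _build_event_context(
            left, right, insert, rec.chrom, rec.pos, config.tsd_length
        )
        bias = config.end_bias.get(rec.transposon)
        for k in range(n_frags):
            frag_len = int(
                max(2 * ell, round(rng.normal(params.frag_mean, params.frag_sd)))
            )
            h = int(rng.integers(-(frag_len - 1), LI))
            if bias is not None:
                kind = _junction_kind(h, frag_len, LI)
                if kind is not None:
                    # weights are per transposon 5'/3' end; map via strand
                    w5, w3 = bias
                    w = (
                        w5
                        if (kind == "left") == (rec.strand == "+")
                        else w3
                    )
                    if rng.random() > w:
                        continue
            pair = _event_fragment_pair(ctx, h, frag_len, params, rng, f"{ev_id}_{k}")
            if pair.r1.mapped or pair.r2.mapped:
                featured.append(pair)
            else:
                unanchored.append(pair)

    events = list(population.germline) + list(population.somatic)
    if events:
        li = np.array(
            [ev.insert_length for ev in events], dtype=np.float64
        )
        p_carrier = np.array([ev.frequency for ev in events])
        lam = rate_per_bp * p_carrier * (li + params.frag_mean - 1)
        counts = rng.poisson(lam)
        for i, ev in enumerate(events):
            handle_event(ev, int(counts[i]), f"ev{i}")

    # --- assemble bulk arrays --------------------------------------------
    if bulk_parts:
        bulk = BulkPairs(
            chrom_id=np.concatenate([p[0] for p in bulk_parts]),
            start1=np.concatenate([p[1] for p in bulk_parts]),
            end1=np.concatenate([p[2] for p in bulk_parts]),
            start2=np.concatenate([p[3] for p in bulk_parts]),
            end2=np.concatenate([p[4] for p in bulk_parts]),
            tlen=np.concatenate([p[5] for p in bulk_parts]),
            proper=np.ones(sum(p[1].size for p in bulk_parts), dtype=bool),
        )
    else:
        bulk = BulkPairs.empty()

    # --- chimeric pairs ---------------------------------------------------
    if config.chimera_rate > 0:
        bulk, chim_feat, chim_unanch = _inject_chimeras_scaled(
            bulk, featured, unanchored, chroms, config.chimera_rate, ell, rng
        )
        featured.extend(chim_feat)
        unanchored.extend(chim_unanch)

    unanchored_list = unanchored
    return ReadSet(
        chroms,
        chrom_lengths,
        bulk,
        featured,
        unanchored=(lambda: iter(unanchored_list)),
        read_length=ell,
    )


# ---------------------------------------------------------------------------
# Chimeras
# ---------------------------------------------------------------------------

def _clone_read(rec: AlignmentRecord, qname: str, read_index: int) -> AlignmentRecord:
    return AlignmentRecord(
        qname=qname, read_index=read_index, mapped=rec.mapped, chrom=rec.chrom,
        pos=rec.pos, strand=rec.strand, mapq=rec.mapq, cigar=list(rec.cigar),
        seq=rec.seq, is_secondary=False, is_supplementary=False,
        mate_chrom=None, mate_pos=-1, mate_mapped=False, proper_flag=False,
        tlen=0,
    )


def _bulk_read(
    bulk: BulkPairs, chroms: Sequence[str], pair_idx: int, which: int,
    qname: str, read_index: int,
) -> AlignmentRecord:
    chrom = chroms[int(bulk.chrom_id[pair_idx])]
    if which == 0:
        pos, end, strand = int(bulk.start1[pair_idx]), int(bulk.end1[pair_idx]), "+"
    else:
        pos, end, strand = int(bulk.start2[pair_idx]), int(bulk.end2[pair_idx]), "-"
    return AlignmentRecord(
        qname=qname, read_index=read_index, mapped=True, chrom=chrom, pos=pos,
        strand=strand, mapq=60, cigar=[("M", end - pos)], seq=None,
        is_secondary=False, is_supplementary=False, mate_chrom=None,
        mate_pos=-1, mate_mapped=False, proper_flag=False, tlen=0,
    )


def _inject_chimeras_scaled(
    bulk: BulkPairs,
    featured: list[ReadPairRecord],
    unanchored: list[ReadPairRecord],
    chroms: Sequence[str],
    rate: float,
    read_length: int,
    rng: np.random.Generator,
) -> tuple[BulkPairs, list[ReadPairRecord], list[ReadPairRecord]]:
    """Replace a fraction ``rate`` of pairs with chimeras joining two
    random reads of the library."""
    n_bulk = len(bulk)
    objects = featured + unanchored
    total_pairs = n_bulk + len(objects)
    if total_pairs == 0:
        return bulk, [], []
    n_chim = rng.binomial(total_pairs, rate)
    if n_chim == 0:
        return bulk, [], []

    new_feat: list[ReadPairRecord] = []
    new_unanch: list[ReadPairRecord] = []
    total_reads = 2 * total_pairs
    for i in range(int(n_chim)):
        reads = []
        for ri in (1, 2):
            g = int(rng.integers(0, total_reads))
            pair_idx, which = g // 2, g % 2
            qname = f"chim{i}"
            if pair_idx < n_bulk:
                reads.append(_bulk_read(bulk, chroms, pair_idx, which, qname, ri))
            else:
                src = objects[pair_idx - n_bulk].reads[which]
                reads.append(_clone_read(src, qname, ri))
        pair = _finalise_pair(reads[0], reads[1])
        # a chimera's reads come from unrelated fragments: never proper
        pair.r1.proper_flag = pair.r2.proper_flag = False
        pair.is_chimera_truth = True
        if pair.r1.mapped or pair.r2.mapped:
            new_feat.append(pair)
        else:
            new_unanch.append(pair)

    # the chimeras replace pairs; remove as many from the bulk
    n_drop = min(int(n_chim), n_bulk)
    if n_drop:
        drop = rng.choice(n_bulk, size=n_drop, replace=False)
        keep = np.ones(n_bulk, dtype=bool)
        keep[drop] = False
        bulk = BulkPairs(
            chrom_id=bulk.chrom_id[keep], start1=bulk.start1[keep],
            end1=bulk.end1[keep], start2=bulk.start2[keep],
            end2=bulk.end2[keep], tlen=bulk.tlen[keep], proper=bulk.proper[keep],
        )
    return bulk, new_feat, new_unanch


def inject_chimeras(
    pairs: list[ReadPairRecord],
    rate: float,
    seed: int | np.random.Generator = 0,
) -> tuple[list[ReadPairRecord], int]:
    """Object-level chimera injection for small pair lists.

    A fraction ``rate`` of pairs is replaced by pairs combining two
    random reads drawn from the library; replaced-in pairs carry the
    ``is_chimera_truth`` flag.  Returns (pairs, number of chimeras).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    n = len(pairs)
    n_chim = rng.binomial(n, rate) if rate > 0 else 0
    if n_chim == 0:
        return list(pairs), 0
    out = list(pairs)
    replaced = rng.choice(n, size=int(n_chim), replace=False)
    for i, slot in enumerate(sorted(int(r) for r in replaced)):
        reads = []
        for ri in (1, 2):
            g = int(rng.integers(0, 2 * n))
            src = pairs[g // 2].reads[g % 2]
            reads.append(_clone_read(src, f"chim{i}", ri))
        pair = _finalise_pair(reads[0], reads[1])
        pair.r1.proper_flag = pair.r2.proper_flag = False
        pair.is_chimera_truth = True
        out[slot] = pair
    return out, int(n_chim)


# ---------------------------------------------------------------------------
# Truth outputs
# ---------------------------------------------------------------------------

def emit_truth(population: Population, out_dir: str | Path) -> dict[str, Path]:
    """Write germline truth BED and somatic per-family truth TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bed = out_dir / "germline_truth.bed"
    with open(bed, "w") as fh:
        for rec in sorted(population.germline, key=lambda r: (r.chrom, r.pos)):
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.pos + 1}\t{rec.transposon}\t"
                f"{rec.frequency}\t{rec.strand}\t{rec.te_start}\t{rec.te_end}\n"
            )
    tsv = out_dir / "somatic_truth.tsv"
    counts = population.somatic_counts_per_genome()
    with open(tsv, "w") as fh:
        fh.write("family\tinsertions_per_genome\ttotal_insertions\n")
        for fam in sorted(counts):
            fh.write(
                f"{fam}\t{counts[fam]}\t"
                f"{counts[fam] * population.config.n_genomes:.0f}\n"
            )
    return {"germline_bed": bed, "somatic_tsv": tsv}


def write_truth_sam(
    readset: ReadSet,
    population: Population,
    path: str | Path,
    seed: int | np.random.Generator = 0,
) -> None:
    """Materialise the full library as a truth SAM file (small scales).

    Bulk reference pairs get sequences sliced from the reference with
    fresh simulated errors; featured pairs are written as generated.
    """
    import pysam

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params = population.config.read
    chrom_seq = {g.name: g.sequence for g in population.genome}
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": readset.chrom_lengths[name]}
            for name in readset.chroms
        ],
    }
    refid = {name: i for i, name in enumerate(readset.chroms)}

    def to_pysam(rec: AlignmentRecord, mate: AlignmentRecord):
        a = pysam.AlignedSegment()
        a.query_name = rec.qname
        flag = 0x1
        flag |= 0x40 if rec.read_index == 1 else 0x80
        if not rec.mapped:
            flag |= 0x4
        elif rec.strand == "-":
            flag |= 0x10
        if not mate.mapped:
            flag |= 0x8
        elif mate.strand == "-":
            flag |= 0x20
        if rec.proper_flag:
            flag |= 0x2
        a.flag = flag
        if rec.mapped:
            a.reference_id = refid[rec.chrom]
            a.reference_start = rec.pos
            a.mapping_quality = rec.mapq
            a.cigarstring = "".join(f"{n}{op}" for op, n in rec.cigar)
        elif mate.mapped:
            a.reference_id = refid[mate.chrom]
            a.reference_start = mate.pos
        if mate.mapped:
            a.next_reference_id = refid[mate.chrom]
            a.next_reference_start = mate.pos
        elif rec.mapped:
            a.next_reference_id = refid[rec.chrom]
            a.next_reference_start = rec.pos
        a.template_length = rec.tlen
        seq = rec.seq
        if seq is not None:
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        return a

    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        bulk = readset.bulk
        ell = params.read_length
        for i in range(len(bulk)):
            chrom = readset.chroms[int(bulk.chrom_id[i])]
            seq = chrom_seq[chrom]
            qname = f"ref{i}"
            s1, s2 = int(bulk.start1[i]), int(bulk.start2[i])
            e2 = int(bulk.end2[i])
            seq1 = _apply_errors(seq[s1 : s1 + ell], rng, params.error_rate)
            seq2 = _apply_errors(seq[e2 - ell : e2], rng, params.error_rate)
            tlen = int(bulk.tlen[i])
            r1 = AlignmentRecord(
                qname=qname, read_index=1, mapped=True, chrom=chrom, pos=s1,
                strand="+", mapq=60, cigar=[("M", ell)], seq=seq1,
                is_secondary=False, is_supplementary=False, mate_chrom=chrom,
                mate_pos=s2, mate_mapped=True, proper_flag=True, tlen=tlen,
            )
            r2 = AlignmentRecord(
                qname=qname, read_index=2, mapped=True, chrom=chrom, pos=s2,
                strand="-", mapq=60, cigar=[("M", ell)], seq=seq2,
                is_secondary=False, is_supplementary=False, mate_chrom=chrom,
                mate_pos=s1, mate_mapped=True, proper_flag=True, tlen=-tlen,
            )
            out.write(to_pysam(r1, r2))
            out.write(to_pysam(r2, r1))
        for pair in list(readset.featured) + list(readset.iter_unanchored()):
            out.write(to_pysam(pair.r1, pair.r2))
            out.write(to_pysam(pair.r2, pair.r1))


def export_fastq(
    readset: ReadSet,
    population: Population,
    path1: str | Path,
    path2: str | Path,
    seed: int | np.random.Generator = 0,
) -> None:
    """Optional FASTQ export for end-to-end runs with a real aligner."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params = population.config.read
    ell = params.read_length
    chrom_seq = {g.name: g.sequence for g in population.genome}
    qual = "I" * ell
    with open(path1, "w") as f1, open(path2, "w") as f2:
        bulk = readset.bulk
        for i in range(len(bulk)):
            chrom = readset.chroms[int(bulk.chrom_id[i])]
            seq = chrom_seq[chrom]
            s1, e2 = int(bulk.start1[i]), int(bulk.end2[i])
            seq1 = _apply_errors(seq[s1 : s1 + ell], rng, params.error_rate)
            seq2 = _revcomp(_apply_errors(seq[e2 - ell : e2], rng, params.error_rate))
            f1.write(f"@ref{i}/1\n{seq1}\n+\n{qual}\n")
            f2.write(f"@ref{i}/2\n{seq2}\n+\n{qual}\n")
        for pair in list(readset.featured) + list(readset.iter_unanchored()):
            for rec, fh in ((pair.r1, f1), (pair.r2, f2)):
                seq = rec.read_oriented_seq()
                if seq is None:
                    continue
                fh.write(f"@{rec.qname}/{rec.read_index}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def simulate_calibration_events(
    f95: float,
    coverage_per_genome: float,
    read_length: int = 100,
    frag_mean: float = 450.0,
    frag_sd: float = 10.0,
    error_rate: float = 0.001,
    n_events: int = 200_000,
    read_density: float | None = None,
    te_length: int = 2000,
    seed: int = 0,
) -> float:
    """Measure the singleton-end read yield of one single-genome insertion.

    ``n_events`` independent insertions of a synthetic transposon are
    placed on a virtual coordinate space (random flanking sequence per
    event), reads are drawn at ``coverage_per_genome``, the caller's
    clustering and the end/center tally run as in a real analysis, and
    the number of surviving singleton end-mapping reads per event is
    returned.  This is the empirical ``r_exp`` for a dataset with the
    same read geometry and singleton read density.
    """
    from .calling import CallerConfig, call_insertions
    from .denovo import define_end_regions, tally_end_center

    rng = np.random.default_rng(seed)
    params = ReadSimParams(
        read_length=read_length, frag_mean=frag_mean, frag_sd=frag_sd,
        error_rate=error_rate,
    )
    lib_rng = np.random.default_rng(rng.integers(0, 2**31))
    library = ConsensusLibrary({"CAL_TE": _random_dna(lib_rng, te_length)})
    insert_fwd = library.entries["CAL_TE"]
    insert_rev = _revcomp(insert_fwd)

    # virtual genome long enough to reproduce the requested read density
    exp_yield = coverage_per_genome * (frag_mean - params.min_anchor - 10) / read_length
    if read_density is None or read_density <= 0:
        genome_len = int(n_events * 5000)
    else:
        genome_len = max(int(n_events * exp_yield / read_density), 10 * frag_mean)
    pad = params.frag_max + 16

    positions = rng.integers(pad, genome_len - pad, size=n_events)
    lam = (
        coverage_per_genome / (2 * read_length)
        * (te_length + frag_mean - 1)
    )
    counts = rng.poisson(lam, size=n_events)
    featured: list[ReadPairRecord] = []
    unanchored: list[ReadPairRecord] = []
    for i in np.nonzero(counts)[0]:
        b = int(positions[i])
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        insert = insert_fwd if strand == "+" else insert_rev
        ctx = _build_event_context(
            _random_dna(rng, pad), _random_dna(rng, pad), insert, "cal", b, 0
        )
        for k in range(int(counts[i])):
            frag_len = int(
                max(2 * read_length, round(rng.normal(frag_mean, frag_sd)))
            )
            h = int(rng.integers(-(frag_len - 1), te_length))
            pair = _event_fragment_pair(ctx, h, frag_len, params, rng, f"cal{i}_{k}")
            if pair.r1.mapped or pair.r2.mapped:
                featured.append(pair)
            else:
                unanchored.append(pair)

    readset = ReadSet(
        ["cal"], {"cal": genome_len}, BulkPairs.empty(), featured,
        unanchored=(lambda: iter(unanchored)), read_length=read_length,
    )
    config = CallerConfig(f95=f95, coverage_filter=False)
    result = call_insertions(readset, library, config=config)
    spec = define_end_regions(library, f95)
    tallies = tally_end_center(
        result.singleton_reads(), [], spec, library, orientation_check=True
    )
    return tallies["CAL_TE"].SE / n_events
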