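"""Curate a transposon-insertion benchmark from long-read alignments.

Constructs synthetic long reads over a genome with one homozygous and
one 50%-frequency insertion, writes them as SAM, and runs the curation:
CIGAR insertion extraction (>= 300 bp), consensus validation, 50-bp
merging, >= 2-read filtering, and S/(S+2R) frequency estimation.
"""

import numpy as np
import pysam

from tescan import ConsensusLibrary, curate_benchmark
from tescan.simulate import _random_dna, random_genome

rng = np.random.default_rng(4)
genome = random_genome(200_000, rng)
library = ConsensusLibrary({"TE_A": _random_dna(rng, 4000), "TE_B": _random_dna(rng, 2500)})

header = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 200_000}]}
)


def long_read(qname, bp, insert=None, flank=2000):
    a = pysam.AlignedSegment(header)
    a.query_name = qname
    a.reference_id = 0
    a.mapping_quality = 60
    a.reference_start = bp - flank
    if insert is None:
        a.cigarstring = f"{2 * flank}M"
        a.query_sequence = genome.sequence[bp - flank : bp + flank]
    else:
        a.cigarstring = f"{flank}M{len(insert)}I{flank}M"
        a.query_sequence = (
            genome.sequence[bp - flank : bp] + insert + genome.sequence[bp : bp + flank]
        )
    a.query_qualities = pysam.qualitystring_to_array("I" * len(a.query_sequence))
    return a


bp_hom, bp_het = 50_000, 150_000
with pysam.AlignmentFile("example_longreads.sam", "wh", header=header) as out:
    for i in range(6):  # homozygous: every read carries the insertion
        out.write(long_read(f"hom{i}", bp_hom, library.entries["TE_A"]))
    for i in range(8):  # heterozygous: half the reads carry it
        insert = library.entries["TE_B"] if i % 2 == 0 else None
        out.write(long_read(f"het{i}", bp_het, insert))

curated = curate_benchmark("example_longreads.sam", library)
print(f"{'breakpoint':>10} {'TE':>5} {'reads':>5} {'freq':>6} {'te span':>12}")
for ins in curated:
    print(
        f"{ins.breakpoint:>10} {ins.transposon:>5} {ins.n_supporting:>5} "
        f"{ins.frequency:>6.3f} {ins.te_start:>5}-{ins.te_end}"
    )
# A read whose insertion op sits at the breakpoint splits at both ends
# of the inserted transposon and counts as two supporting reads, so the
# homozygous site estimates frequency 1.0 and the 50% site ~0.5.
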