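"""Self-contained benchmark experiments on synthetic data.

These functions reproduce, at reduced genome scale, the two simulation
experiments used to validate the method: germline insertion detection
(400 insertions at frequencies 0.25-1 on a 4-Mb genome) and genome-wide
de novo rate estimation (per-genome somatic insertion counts
8/4/3/2/1/1/1 across 10,000 genomes).  Reads are 100-nt pairs from
450 +- 10 nt fragments at 20x total depth with 0.05% chimeric pairs.

The de novo experiment runs on a 40-Mb genome: the somatic singleton
read density scales inversely with genome size, and below ~20 Mb an
appreciable fraction of genuine singletons from the densest family would
cluster with each other and leave the singleton tally — an artifact of
over-shrinking the genome, not a property of the method.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .calling import CallerConfig, call_insertions
from .denovo import calibrate_singleton_yield, estimate_denovo_rates
from .metrics import (
    MatchSpec,
    breakpoint_distance,
    de_novo_correlation,
    de_novo_ssr,
    detection_metrics,
    frequency_error,
    match_calls,
    te_end_distance,
)
from .simulate import (
    GermlineSpec,
    SimulationConfig,
    SomaticFamilySpec,
    build_population,
    random_genome,
    simulate_read_pairs,
    synthetic_library,
)

SOMATIC_COUNTS = (8, 4, 3, 2, 1, 1, 1)
PARTIAL_COUNT = 2  # the count-2 family transposes as a truncated fragment


@dataclass
class GermlineExperimentResult:
    sensitivity: float
    precision: float
    f1: float
    mean_frequency_error: float
    mean_breakpoint_distance: float
    fraction_accurate_breakpoints: float
    mean_te_end_distance: float
    n_truth: int
    n_calls: int
    n_matched: int


def run_germline_experiment(
    seed: int,
    depth: float = 20.0,
    genome_length: int = 4_000_000,
    n_te: int = 48,
    n_insertions: int = 400,
    n_genomes: int = 10_000,
    chimera_rate: float = 5e-4,
    min_support: int = 5,
) -> GermlineExperimentResult:
    """Simulate the germline benchmark and score the caller against truth."""
    rng = np.random.default_rng(seed)
    genome = [random_genome(genome_length, rng)]
    library = synthetic_library(n_te, (1500, 7500), rng)
    config = SimulationConfig(
        n_genomes=n_genomes,
        depth=depth,
        germline=GermlineSpec(n_insertions=n_insertions),
        somatic=[],
        chimera_rate=chimera_rate,
    )
    population = build_population(genome, library, config, rng)
    readset = simulate_read_pairs(population, rng)
    result = call_insertions(readset, library, config=CallerConfig(min_support=min_support))
    calls = result.germline_calls(min_support=min_support)
    spec = MatchSpec(max_distance=50, family_aware=True)
    sens, prec, f1 = detection_metrics(calls, population.germline, spec)
    matches = match_calls(calls, population.germline, spec)
    mean_bp, frac_acc = breakpoint_distance(matches)
    return GermlineExperimentResult(
        sensitivity=sens,
        precision=prec,
        f1=f1,
        mean_frequency_error=frequency_error(matches),
        mean_breakpoint_distance=mean_bp,
        fraction_accurate_breakpoints=frac_acc,
        mean_te_end_distance=te_end_distance(matches),
        n_truth=len(population.germline),
        n_calls=len(calls),
        n_matched=len(matches),
    )


@dataclass
class DeNovoExperimentResult:
    ssr: float
    pearson_r: float
    estimates: dict[str, float] = field(default_factory=dict)
    truth: dict[str, float] = field(default_factory=dict)
    r_exp: float = 0.0
    n_families: int = 0
    n_singletons: int = 0


def run_denovo_experiment(
    seed: int,
    depth: float = 20.0,
    genome_length: int = 40_000_000,
    n_te: int = 48,
    n_genomes: int = 10_000,
    chimera_rate: float = 5e-4,
    counts: tuple[int, ...] = SOMATIC_COUNTS,
    calibrate: bool = True,
    calibration_events: int = 800_000,
) -> DeNovoExperimentResult:
    """Simulate the somatic benchmark and recover per-family rates.

    The read-to-insertion conversion factor (r_exp) is calibrated with
    the simulator at the dataset's own per-genome coverage and singleton
    read density; set ``calibrate=False`` for the analytic value.
    """
    rng = np.random.default_rng(seed)
    genome = [random_genome(genome_length, rng)]
    library = synthetic_library(n_te, (1500, 7500), rng)
    eligible = [n for n in library.names if len(library.entries[n]) >= 2500]
    chosen = [str(t) for t in rng.choice(eligible, size=len(counts), replace=False)]
    somatic = [
        SomaticFamilySpec(te, c, partial=(c == PARTIAL_COUNT))
        for te, c in zip(chosen, counts)
    ]
    config = SimulationConfig(
        n_genomes=n_genomes, depth=depth, germline=None,
        somatic=somatic, chimera_rate=chimera_rate,
    )
    population = build_population(genome, library, config, rng)
    readset = simulate_read_pairs(population, rng)
    result = call_insertions(readset, library)
    singles = result.singleton_reads()

    coverage_per_genome = depth / n_genomes
    if calibrate:
        family_counts = Counter(r.family for r in singles)
        total = sum(family_counts.values())
        genome_total = sum(readset.chrom_lengths.values())
        density = (
            sum(c * (c / genome_total) for c in family_counts.values()) / total
            if total
            else None
        )
        r_exp = calibrate_singleton_yield(
            f95=result.f95,
            coverage_per_genome=coverage_per_genome,
            frag_mean=config.read.frag_mean,
            frag_sd=config.read.frag_sd,
            error_rate=config.read.error_rate,
            read_length=config.read.read_length,
            n_events=calibration_events,
            read_density=density,
            seed=int(rng.integers(0, 2**31)),
        )
    else:
        r_exp = None

    estimates = estimate_denovo_rates(
        result, readset, library,
        n_genomes=n_genomes, depth=depth, r_exp=r_exp,
        frag_mean=config.read.frag_mean,
        discover_fragments=True,
    )
    est = {fam: e.insertions_per_genome for fam, e in estimates.items()}
    truth = population.somatic_counts_per_genome()
    return DeNovoExperimentResult(
        ssr=de_novo_ssr(est, truth),
        pearson_r=de_novo_correlation(est, truth),
        estimates=est,
        truth=truth,
        r_exp=r_exp if r_exp is not None else 0.0,
        n_families=len(truth),
        n_singletons=len(singles),
    )
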