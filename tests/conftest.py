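"""Shared simulated scenarios.

The planted-truth fixtures simulate full XY/ZW/no-GSD populations once
per session; individual tests then interrogate different downstream
views of the same data.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from sexsignal import kmersex, poolsig, radmarkers, simpop

ENZYME = simpop.DEFAULT_ENZYME_SITE
READ_LENGTH = 80


@dataclass
class Scenario:
    pair: simpop.HaplotypePair
    pop: simpop.PopulationSim
    reads: dict[str, list[str]]
    table: radmarkers.MarkerDepthTable
    sites: poolsig.PooledSiteCounts
    kmer_male: kmersex.KmerCounts
    kmer_female: kmersex.KmerCounts


def simulate_scenario(
    system: str,
    chrom_length: int,
    locus_start: int,
    locus_length: int,
    n_males: int,
    n_females: int,
    seed: int,
    depth: float = 30.0,
    theta: float = 0.001,
    error_rate: float = 0.001,
    snp_divergence: float = 0.0,
    with_kmers: bool = True,
) -> Scenario:
    ref = simpop.simulate_reference(1, chrom_length, seed=seed)
    spec = simpop.SexLocusSpec(
        simpop.SDSystem(system),
        "chr1" if system != "NONE" else "",
        locus_start if system != "NONE" else 0,
        locus_length if system != "NONE" else 0,
        snp_divergence,
    )
    sys_enum = simpop.SDSystem(system)
    pair = simpop.plant_sex_locus(
        ref,
        spec,
        seed=seed,
        enzyme_site=ENZYME,
        planted_motifs=3 if sys_enum.is_insertion else 0,
    )
    pop = simpop.simulate_individuals(
        pair, n_males, n_females, theta=theta, sex_reversal_rate=0.0, seed=seed
    )
    reads = simpop.simulate_rad_reads(
        pop,
        enzyme_site=ENZYME,
        read_length=READ_LENGTH,
        mean_depth=depth,
        error_rate=error_rate,
        seed=seed,
    )
    table = radmarkers.build_marker_table(reads, pop.popmap)
    sites = simpop.simulate_pool_pileup(
        pop, mean_depth=depth, error_rate=error_rate, seed=seed
    )
    if with_kmers:
        km, kf = simpop.simulate_kmer_counts(pop, k=31, seed=seed)
    else:
        km = kf = kmersex.count_canonical_kmers([], k=31)
    return Scenario(pair, pop, reads, table, sites, km, kf)


@pytest.fixture(scope="session")
def xy_small():
    """200 kb genome, 20 kb Y insertion, 10M+10F — fast planted truth."""
    return simulate_scenario("XY_INSERTION", 200_000, 100_000, 20_000, 10, 10, seed=3)


@pytest.fixture(scope="session")
def none_small():
    """200 kb genome, no genetic sex determination, 10M+10F."""
    return simulate_scenario("NONE", 200_000, 0, 0, 10, 10, seed=3)
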