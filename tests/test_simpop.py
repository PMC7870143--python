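"""Synthetic population generator: determinism, planted truth, polarity."""

import numpy as np
import pytest

from sexsignal import kmersex, poolsig, simpop
from sexsignal.simpop import SDSystem, SexLocusSpec


def test_reference_fixed_seed_is_byte_identical():
    a = simpop.simulate_reference(1, 10_000, seed=1)
    b = simpop.simulate_reference(1, 10_000, seed=1)
    assert a == b
    assert a != simpop.simulate_reference(1, 10_000, seed=2)


def test_reference_record_shapes():
    ref = simpop.simulate_reference(2, 50_000, seed=7)
    assert [name for name, _ in ref] == ["chr1", "chr2"]
    assert all(len(seq) == 50_000 for _, seq in ref)


def test_reference_composition_is_uniform():
    (_, seq), = simpop.simulate_reference(1, 1_000_000, seed=3)
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert 0.49 < gc < 0.51


def test_reference_parameter_errors():
    with pytest.raises(ValueError):
        simpop.simulate_reference(0, 10_000, seed=1)
    with pytest.raises(ValueError):
        simpop.simulate_reference(1, 500, seed=1)


def test_plant_none_yields_identical_haplotypes():
    ref = simpop.simulate_reference(1, 20_000, seed=1)
    pair = simpop.plant_sex_locus(ref, SexLocusSpec(), seed=1)
    assert pair.hom == pair.het


def test_insertion_length_arithmetic_and_motif_scrub():
    ref = simpop.simulate_reference(1, 200_000, seed=1)
    spec = SexLocusSpec(SDSystem.XY_INSERTION, "chr1", 50_000, 100_000)
    pair = simpop.plant_sex_locus(
        ref, spec, seed=1, enzyme_site="CCTGCAGG", planted_motifs=0
    )
    assert len(pair.het["chr1"]) == len(pair.hom["chr1"]) + 100_000
    assert pair.het["chr1"][:50_000] == pair.hom["chr1"][:50_000]
    assert "CCTGCAGG" not in pair.insert_seq


def test_planted_motif_count_inside_insertion():
    ref = simpop.simulate_reference(1, 100_000, seed=1)
    spec = SexLocusSpec(SDSystem.XY_INSERTION, "chr1", 50_000, 30_000)
    pair = simpop.plant_sex_locus(
        ref, spec, seed=1, enzyme_site="CCTGCAGG", planted_motifs=3
    )
    assert pair.insert_seq.count("CCTGCAGG") == 3


def test_snp_divergence_matches_binomial_expectation():
    ref = simpop.simulate_reference(1, 100_000, seed=2)
    spec = SexLocusSpec(SDSystem.XY_SNP, "chr1", 10_000, 50_000, snp_divergence=0.01)
    pair = simpop.plant_sex_locus(ref, spec, seed=11)
    ham = sum(a != b for a, b in zip(pair.hom["chr1"], pair.het["chr1"]))
    assert 400 <= ham <= 600  # central interval of Binomial(50000, 0.01)
    assert ham == pair.planted_snp_positions.size


def test_locus_out_of_bounds_rejected():
    ref = simpop.simulate_reference(1, 20_000, seed=1)
    spec = SexLocusSpec(SDSystem.XY_SNP, "chr1", 15_000, 10_000, snp_divergence=0.01)
    with pytest.raises(ValueError):
        simpop.plant_sex_locus(ref, spec, seed=1)


def _pair(system=SDSystem.XY_INSERTION, seed=1):
    ref = simpop.simulate_reference(1, 50_000, seed=seed)
    if system is SDSystem.NONE:
        return simpop.plant_sex_locus(ref, SexLocusSpec(), seed=seed)
    spec = SexLocusSpec(system, "chr1", 20_000, 5_000)
    return simpop.plant_sex_locus(
        ref, spec, seed=seed, enzyme_site="CCTGCAGG", planted_motifs=2
    )


def test_no_reversal_makes_phenotypic_males_carriers():
    pop = simpop.simulate_individuals(_pair(), 10, 10, sex_reversal_rate=0.0, seed=1)
    for ind in pop.individuals:
        assert ind.carrier == (ind.phenotypic_sex == "M")


def test_full_reversal_makes_phenotypic_males_noncarriers():
    pop = simpop.simulate_individuals(_pair(), 10, 10, sex_reversal_rate=1.0, seed=1)
    for ind in pop.individuals:
        assert ind.carrier == (ind.phenotypic_sex == "F")


def test_partial_reversal_discordance_in_binomial_interval():
    pop = simpop.simulate_individuals(_pair(), 30, 30, sex_reversal_rate=0.1, seed=5)
    discordant = sum(
        1 for i in pop.individuals if i.genotypic_sex != i.phenotypic_sex
    )
    assert 1 <= discordant <= 11  # 99% interval of Binomial(60, 0.1)


def test_empty_population_rejected():
    with pytest.raises(ValueError):
        simpop.simulate_individuals(_pair(), 0, 0, seed=1)


def test_zw_polarity_carriers_are_females():
    pop = simpop.simulate_individuals(
        _pair(SDSystem.ZW_INSERTION), 10, 10, sex_reversal_rate=0.0, seed=1
    )
    for ind in pop.individuals:
        assert ind.carrier == (ind.phenotypic_sex == "F")


def test_error_free_reads_from_one_locus_are_identical():
    pair = _pair()
    pop = simpop.simulate_individuals(pair, 2, 2, theta=0.0, seed=1)
    reads = simpop.simulate_rad_reads(
        pop, read_length=60, mean_depth=50, error_rate=0.0, seed=1
    )
    max_loci = max(
        len(simpop._rad_loci(pair.het, "CCTGCAGG", 60)),
        len(simpop._rad_loci(pair.hom, "CCTGCAGG", 60)),
    )
    for ind_reads in reads.values():
        assert len(set(ind_reads)) <= max_loci


def test_absent_motif_warns_and_returns_no_reads():
    pop = simpop.simulate_individuals(_pair(), 2, 2, seed=1)
    with pytest.warns(UserWarning):
        reads = simpop.simulate_rad_reads(pop, enzyme_site="AAAAAAAAAAAAAAAAAAAA")
    assert all(not r for r in reads.values())
    with pytest.raises(ValueError):
        simpop.simulate_rad_reads(pop, enzyme_site="")


def test_insertion_rad_loci_appear_in_carriers_only(xy_small):
    truth = set(simpop.insertion_marker_sequences(xy_small.pair, read_length=80))
    females = set(xy_small.pop.popmap.females)
    for ind, ind_reads in xy_small.reads.items():
        if ind in females:
            assert truth.isdisjoint(ind_reads)


def test_none_pileup_without_variation_is_monoallelic():
    ref = simpop.simulate_reference(1, 20_000, seed=4)
    pair = simpop.plant_sex_locus(ref, SexLocusSpec(), seed=4)
    pop = simpop.simulate_individuals(pair, 3, 3, theta=0.0, seed=4)
    sites = simpop.simulate_pool_pileup(pop, mean_depth=20, error_rate=0.0, seed=4)
    assert ((sites.male > 0).sum(axis=1) <= 1).all()
    assert ((sites.female > 0).sum(axis=1) <= 1).all()


def test_insertion_pileup_depth_profile(xy_small):
    locus = xy_small.pair.locus
    sel = slice(locus.start, locus.start + locus.length)
    female_depth = xy_small.sites.female.sum(axis=1)[sel]
    assert female_depth.sum() == 0
    male_depth = xy_small.sites.male.sum(axis=1)
    autosomal = np.r_[male_depth[: locus.start], male_depth[locus.start + locus.length :]]
    ratios = [
        male_depth[locus.start + k : locus.start + k + 1000].mean() / autosomal.mean()
        for k in range(0, locus.length, 1000)
    ]
    ok = sum(1 for r in ratios if 0.4 <= r <= 0.6)
    assert ok / len(ratios) >= 0.9


def test_identical_pools_have_no_specific_kmers(none_small):
    ms, fs = kmersex.merge_and_filter(none_small.kmer_male, none_small.kmer_female)
    assert ms == [] and fs == []


def test_kmer_table_determinism_and_k_bound():
    pair = _pair()
    pop = simpop.simulate_individuals(pair, 3, 3, seed=2)
    a = simpop.simulate_kmer_counts(pop, k=31, seed=2)
    b = simpop.simulate_kmer_counts(pop, k=31, seed=2)
    assert np.array_equal(a[0].codes, b[0].codes)
    assert np.array_equal(a[0].counts, b[0].counts)
    with pytest.raises(ValueError):
        simpop.simulate_kmer_counts(pop, k=100_000, seed=2)


def test_pileup_and_reads_fixed_seed_determinism():
    pair = _pair()
    pop = simpop.simulate_individuals(pair, 3, 3, seed=2)
    s1 = simpop.simulate_pool_pileup(pop, mean_depth=10, seed=2)
    s2 = simpop.simulate_pool_pileup(pop, mean_depth=10, seed=2)
    assert np.array_equal(s1.male, s2.male) and np.array_equal(s1.female, s2.female)
    r1 = simpop.simulate_rad_reads(pop, mean_depth=10, seed=2)
    r2 = simpop.simulate_rad_reads(pop, mean_depth=10, seed=2)
    assert r1 == r2


def test_polarity_mirror_is_exact():
    def build(system):
        ref = simpop.simulate_reference(1, 60_000, seed=9)
        spec = SexLocusSpec(SDSystem(system), "chr1", 30_000, 8_000)
        pair = simpop.plant_sex_locus(ref, spec, seed=9, enzyme_site="CCTGCAGG",
                                      planted_motifs=2)
        pop = simpop.simulate_individuals(pair, 6, 6, seed=9)
        sites = simpop.simulate_pool_pileup(pop, mean_depth=25, seed=9)
        km, kf = simpop.simulate_kmer_counts(pop, k=31, seed=9)
        return sites, km, kf

    xy_sites, xy_m, xy_f = build("XY_INSERTION")
    zw_sites, zw_m, zw_f = build("ZW_INSERTION")
    assert np.array_equal(xy_sites.male, zw_sites.female)
    assert np.array_equal(xy_sites.female, zw_sites.male)
    assert np.array_equal(xy_m.codes, zw_f.codes)
    assert np.array_equal(xy_m.counts, zw_f.counts)


def test_fastq_and_fasta_io(tmp_path):
    pair = _pair()
    pop = simpop.simulate_individuals(pair, 2, 2, seed=1)
    reads = simpop.simulate_rad_reads(pop, mean_depth=5, seed=1)
    paths = simpop.write_fastq(reads, tmp_path / "reads")
    assert len(paths) == 4
    ref = [("chr1", "ACGT" * 30)]
    simpop.write_fasta(ref, tmp_path / "ref.fa")
    assert simpop.read_fasta(tmp_path / "ref.fa") == ref
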