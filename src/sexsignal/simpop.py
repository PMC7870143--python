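"""Synthetic populations with configurable sex-determination systems.

The generator emulates the data types used to detect sex-linked genomic
regions in wild fish populations:

* a random reference genome;
* a sex locus planted on one haplotype — either a hemizygous insertion
  present only on the sex-limited chromosome (Y or W), or a stretch of
  fixed X/Y (Z/W) nucleotide differences on homologous sequence;
* diploid individuals with genotypic sex, private background SNPs at a
  per-base density theta, and a per-individual sex-reversal probability
  (phenotypic sex flipped relative to genotypic sex);
* single-enzyme RAD reads (fixed-length reads flanking each restriction
  motif, Poisson per-copy depth, uniform substitution errors);
* pooled per-site nucleotide counts for a male pool and a female pool
  (Poisson site depth, reads drawn uniformly from pool chromosome
  copies, so hemizygous sequence is covered at ~half depth in the
  carrier pool and ~zero in the other);
* per-pool canonical k-mer count tables.

Randomness is derived from one master seed with per-stage streams, so
individual stages can be rerun reproducibly. Streams that sample the two
pools are keyed by carrier status (heterogametic vs homogametic group)
rather than by sex label: an XY scenario and its ZW mirror simulated
with the same seed produce identical carrier-group data, only the sex
labels differ.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from ._dna import decode, encode, random_bases, revcomp
from .kmersex import KmerCounts, count_canonical_kmers
from .popmap import FEMALE, MALE, PopMap
from .poolsig import PooledSiteCounts

DEFAULT_ENZYME_SITE = "CCTGCAGG"  # SbfI recognition motif
DEFAULT_THETA = 0.001
DEFAULT_ERROR_RATE = 0.001
#: per-chromosome-copy k-mer coverage used to emulate read-based k-mer
#: counting (~100x pool coverage over 40 copies, lane-scale pooled
#: sequencing); see docs/methods.md
DEFAULT_KMER_DEPTH_PER_COPY = 2.5


class SDSystem(str, Enum):
    XY_INSERTION = "XY_INSERTION"
    XY_SNP = "XY_SNP"
    ZW_INSERTION = "ZW_INSERTION"
    ZW_SNP = "ZW_SNP"
    NONE = "NONE"

    @property
    def is_insertion(self) -> bool:
        return self in (SDSystem.XY_INSERTION, SDSystem.ZW_INSERTION)

    @property
    def is_snp(self) -> bool:
        return self in (SDSystem.XY_SNP, SDSystem.ZW_SNP)

    @property
    def carrier_sex(self) -> str | None:
        """Genotypic sex carrying the sex-limited haplotype."""
        if self in (SDSystem.XY_INSERTION, SDSystem.XY_SNP):
            return MALE
        if self in (SDSystem.ZW_INSERTION, SDSystem.ZW_SNP):
            return FEMALE
        return None


def _rng(seed: int, stage: str) -> np.random.Generator:
    """Per-stage stream derived from the master seed by stable hashing."""
    return np.random.default_rng([int(seed), zlib.crc32(stage.encode())])


@dataclass(frozen=True)
class SexLocusSpec:
    """Location and nature of the planted sex locus (0-based half-open)."""

    system: SDSystem = SDSystem.NONE
    chrom: str = ""
    start: int = 0
    length: int = 0
    snp_divergence: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("locus start must be >= 0")
        if (self.length == 0) != (self.system is SDSystem.NONE):
            raise ValueError("length must be 0 iff system is NONE")
        if self.system.is_snp and not 0 < self.snp_divergence <= 1:
            raise ValueError("SNP systems need snp_divergence in (0, 1]")


def simulate_reference(
    n_chrom: int, chrom_length: int, seed: int
) -> list[tuple[str, str]]:
    """Random reference with uniform base composition; deterministic for
    a fixed seed."""
    if n_chrom < 1 or chrom_length < 10_000:
        raise ValueError("need n_chrom >= 1 and chrom_length >= 10000")
    rng = _rng(seed, "reference")
    return [
        (f"chr{i + 1}", random_bases(rng, chrom_length)) for i in range(n_chrom)
    ]


@dataclass
class HaplotypePair:
    """Homogametic (X/Z) and heterogametic (Y/W) haplotype sets."""

    system: SDSystem
    hom: dict[str, str]  # chromosome ID -> sequence
    het: dict[str, str]
    locus: SexLocusSpec
    insert_seq: str = ""
    planted_snp_positions: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64)
    )


def _scrub_motif(seq: str, motif: str, rng: np.random.Generator) -> str:
    """Destroy every occurrence of motif by mutating one of its bases."""
    codes = list(seq)
    while True:
        idx = "".join(codes).find(motif)
        rc_idx = "".join(codes).find(revcomp(motif))
        hits = [i for i in (idx, rc_idx) if i >= 0]
        if not hits:
            return "".join(codes)
        i = min(hits)
        j = i + int(rng.integers(0, len(motif)))
        old = codes[j]
        choices = [b for b in "ACGT" if b != old]
        codes[j] = choices[int(rng.integers(0, 3))]


def plant_sex_locus(
    reference: list[tuple[str, str]],
    spec: SexLocusSpec,
    seed: int,
    enzyme_site: str | None = None,
    planted_motifs: int = 0,
) -> HaplotypePair:
    """Derive the two sex haplotypes from a reference.

    For insertion systems the heterogametic haplotype gains ``length``
    novel bases at ``start``; the inserted sequence avoids creating new
    copies of ``enzyme_site`` unless ``planted_motifs`` restriction
    motifs are explicitly requested (evenly spaced inside the insertion).
    For SNP systems both haplotypes keep the same length and differ at
    ~``length * snp_divergence`` planted fixed positions.
    """
    hom = dict(reference)
    if spec.system is SDSystem.NONE:
        return HaplotypePair(spec.system, hom, dict(hom), spec)
    if spec.chrom not in hom:
        raise ValueError(f"locus chromosome {spec.chrom!r} not in reference")
    chrom_seq = hom[spec.chrom]
    rng = _rng(seed, "sex-locus")
    het = dict(hom)
    if spec.system.is_insertion:
        if spec.start > len(chrom_seq):
            raise ValueError("insertion start beyond chromosome end")
        insert = random_bases(rng, spec.length)
        if enzyme_site:
            insert = _scrub_motif(insert, enzyme_site, rng)
            if planted_motifs > 0:
                step = spec.length // (planted_motifs + 1)
                chars = list(insert)
                for i in range(planted_motifs):
                    at = (i + 1) * step
                    chars[at : at + len(enzyme_site)] = enzyme_site
                insert = "".join(chars)[: spec.length]
        het[spec.chrom] = (
            chrom_seq[: spec.start] + insert + chrom_seq[spec.start :]
        )
        return HaplotypePair(spec.system, hom, het, spec, insert_seq=insert)
    # SNP system
    if spec.start + spec.length > len(chrom_seq):
        raise ValueError("SNP locus extends beyond chromosome end")
    mask = rng.random(spec.length) < spec.snp_divergence
    positions = np.flatnonzero(mask) + spec.start
    codes = encode(chrom_seq).copy()
    shift = rng.integers(1, 4, size=positions.size).astype(np.uint8)
    codes[positions] = (codes[positions] + shift) % 4
    het[spec.chrom] = decode(codes)
    return HaplotypePair(
        spec.system, hom, het, spec, planted_snp_positions=positions
    )


@dataclass
class Individual:
    id: str
    carrier: bool  # carries the heterogametic haplotype as second copy
    genotypic_sex: str
    phenotypic_sex: str
    # (chrom, copy index) -> (sorted positions in the copy's own frame,
    # alternative base codes)
    snps: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    def copy_is_het(self, copy: int) -> bool:
        return self.carrier and copy == 1


@dataclass
class PopulationSim:
    haplotypes: HaplotypePair
    individuals: list[Individual]
    popmap: PopMap
    n_males: int
    n_females: int
    theta: float
    sex_reversal_rate: float
    seed: int

    @property
    def system(self) -> SDSystem:
        return self.haplotypes.system

    def haplotype_of(self, ind: Individual, copy: int) -> dict[str, str]:
        return self.haplotypes.het if ind.copy_is_het(copy) else self.haplotypes.hom


def _draw_private_snps(
    rng: np.random.Generator, length: int, theta: float
) -> tuple[np.ndarray, np.ndarray]:
    n = rng.binomial(length, theta)
    pos = np.unique(rng.integers(0, length, size=n))
    shift = rng.integers(1, 4, size=pos.size).astype(np.uint8)
    return pos.astype(np.int64), shift  # alt = (ref + shift) % 4


def simulate_individuals(
    pair: HaplotypePair,
    n_males: int,
    n_females: int,
    theta: float = DEFAULT_THETA,
    sex_reversal_rate: float = 0.0,
    seed: int = 0,
) -> PopulationSim:
    """Draw a diploid population from the haplotype pair.

    Genotypic sexes follow the system's polarity (XY: males carry the
    heterogametic haplotype; ZW: females). Each individual's phenotypic
    sex equals its genotypic sex with probability 1 - sex_reversal_rate.
    Background private SNPs are drawn independently per chromosome copy
    at per-base rate theta. Individuals are ordered carriers-first so
    that mirrored polarities share RNG streams.
    """
    if n_males < 0 or n_females < 0 or n_males + n_females == 0:
        raise ValueError("need at least one individual")
    if not 0 <= sex_reversal_rate <= 1:
        raise ValueError("sex_reversal_rate must be in [0, 1]")
    carrier_sex = pair.system.carrier_sex
    if carrier_sex == MALE:
        n_carriers, carrier_geno, other_geno = n_males, MALE, FEMALE
    elif carrier_sex == FEMALE:
        n_carriers, carrier_geno, other_geno = n_females, FEMALE, MALE
    else:  # no genetic sex determination
        n_carriers, carrier_geno, other_geno = 0, MALE, FEMALE

    total = n_males + n_females
    genotypes: list[tuple[bool, str]] = []
    if carrier_sex is None:
        genotypes = [(False, MALE)] * n_males + [(False, FEMALE)] * n_females
    else:
        n_other = total - n_carriers
        genotypes = [(True, carrier_geno)] * n_carriers + [
            (False, other_geno)
        ] * n_other

    rev_rng = _rng(seed, "reversal")
    snp_rng = _rng(seed, "private-snps")
    flip = {MALE: FEMALE, FEMALE: MALE}
    individuals: list[Individual] = []
    for i, (carrier, geno) in enumerate(genotypes):
        if carrier_sex is None:
            pheno = geno  # sexes independent of genotype
            rev_rng.random()  # keep stream alignment across systems
        else:
            pheno = flip[geno] if rev_rng.random() < sex_reversal_rate else geno
        ind = Individual(f"ind{i + 1:03d}", carrier, geno, pheno)
        for chrom in pair.hom:
            for copy in (0, 1):
                hap = pair.het if (carrier and copy == 1) else pair.hom
                ind.snps[(chrom, copy)] = _draw_private_snps(
                    snp_rng, len(hap[chrom]), theta
                )
        individuals.append(ind)
    popmap = PopMap({ind.id: ind.phenotypic_sex for ind in individuals})
    return PopulationSim(
        pair,
        individuals,
        popmap,
        n_males,
        n_females,
        theta,
        sex_reversal_rate,
        seed,
    )


# ---------------------------------------------------------------------------
# RAD reads


@dataclass(frozen=True)
class _RadLocus:
    chrom: str
    start: int  # haplotype coordinates of the read interval, half-open
    end: int
    strand: str  # '+' read downstream of motif; '-' upstream, revcomp


def _rad_loci(hap: dict[str, str], motif: str, read_length: int) -> list[_RadLocus]:
    loci = []
    mlen = len(motif)
    for chrom, seq in hap.items():
        start = 0
        while True:
            idx = seq.find(motif, start)
            if idx < 0:
                break
            if idx + mlen + read_length <= len(seq):
                loci.append(
                    _RadLocus(chrom, idx + mlen, idx + mlen + read_length, "+")
                )
            if idx - read_length >= 0:
                loci.append(_RadLocus(chrom, idx - read_length, idx, "-"))
            start = idx + 1
    return loci


def _locus_read(
    hap: dict[str, str],
    locus: _RadLocus,
    snps: tuple[np.ndarray, np.ndarray],
) -> str:
    seq = hap[locus.chrom][locus.start : locus.end]
    pos, shift = snps
    lo = np.searchsorted(pos, locus.start)
    hi = np.searchsorted(pos, locus.end)
    if hi > lo:
        codes = encode(seq).copy()
        offs = pos[lo:hi] - locus.start
        codes[offs] = (codes[offs] + shift[lo:hi]) % 4
        seq = decode(codes)
    return seq if locus.strand == "+" else revcomp(seq)


def simulate_rad_reads(
    pop: PopulationSim,
    enzyme_site: str = DEFAULT_ENZYME_SITE,
    read_length: int = 80,
    mean_depth: float = 30.0,
    error_rate: float = DEFAULT_ERROR_RATE,
    seed: int | None = None,
) -> dict[str, list[str]]:
    """Single-enzyme RAD reads per individual.

    One locus per motif occurrence per strand; fixed-length reads flank
    the motif. Depth per locus per chromosome copy ~ Poisson(mean/2), so
    diploid loci see ~mean_depth reads and hemizygous (insertion) loci in
    carriers ~mean_depth/2. Uniform per-base substitution errors.
    """
    if not enzyme_site:
        raise ValueError("enzyme motif must be non-empty")
    seed = pop.seed if seed is None else seed
    hom_loci = _rad_loci(pop.haplotypes.hom, enzyme_site, read_length)
    het_loci = _rad_loci(pop.haplotypes.het, enzyme_site, read_length)
    if not hom_loci and not het_loci:
        warnings.warn(f"motif {enzyme_site!r} absent from both haplotypes")
        return {ind.id: [] for ind in pop.individuals}
    rng = _rng(seed, "rad-reads")
    reads: dict[str, list[str]] = {}
    for ind in pop.individuals:
        ind_reads: list[str] = []
        for copy in (0, 1):
            hap = pop.haplotype_of(ind, copy)
            loci = het_loci if ind.copy_is_het(copy) else hom_loci
            for locus in loci:
                depth = rng.poisson(mean_depth / 2.0)
                if depth == 0:
                    continue
                base_read = _locus_read(hap, locus, ind.snps[(locus.chrom, copy)])
                for _ in range(depth):
                    read = base_read
                    if error_rate > 0:
                        n_err = rng.binomial(read_length, error_rate)
                        if n_err:
                            codes = encode(read).copy()
                            at = rng.integers(0, read_length, size=n_err)
                            codes[at] = (
                                codes[at]
                                + rng.integers(1, 4, size=n_err).astype(np.uint8)
                            ) % 4
                            read = decode(codes)
                    ind_reads.append(read)
        reads[ind.id] = ind_reads
    return reads


def insertion_marker_sequences(
    pair: HaplotypePair,
    enzyme_site: str = DEFAULT_ENZYME_SITE,
    read_length: int = 80,
) -> list[str]:
    """Error-free read sequences of RAD loci lying inside a planted
    insertion — the ground-truth sex-limited markers of the scenario."""
    if not pair.system.is_insertion:
        return []
    locus = pair.locus
    lo, hi = locus.start, locus.start + locus.length
    out = []
    for rad in _rad_loci(pair.het, enzyme_site, read_length):
        if rad.chrom == locus.chrom and rad.start >= lo and rad.end <= hi:
            seq = pair.het[rad.chrom][rad.start : rad.end]
            out.append(seq if rad.strand == "+" else revcomp(seq))
    return out


def write_fastq(reads: dict[str, list[str]], outdir: str | Path) -> list[Path]:
    """One FASTQ per individual, constant Phred-33 quality 'I'."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ind, seqs in reads.items():
        path = outdir / f"{ind}.fastq"
        with open(path, "w") as fh:
            for i, seq in enumerate(seqs):
                fh.write(f"@{ind}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Pooled pileup


def _map_hom_to_ref(pos: np.ndarray, locus: SexLocusSpec) -> np.ndarray:
    """Map homogametic-haplotype coordinates into the reference frame
    (the heterogametic haplotype, which contains any insertion)."""
    if locus.system.is_insertion:
        return np.where(pos < locus.start, pos, pos + locus.length)
    return pos


def _pool_pileup_chrom(
    pop: PopulationSim,
    chrom: str,
    members: list[Individual],
    mean_depth: float,
    error_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sampled (n_sites, 4) allele counts for one pool on one chromosome
    of the reference frame (= heterogametic haplotype)."""
    pair = pop.haplotypes
    locus = pair.locus
    het_codes = encode(pair.het[chrom])
    n = het_codes.size
    is_locus_chrom = locus.system.is_insertion and chrom == locus.chrom
    # reference-frame per-site base of a homogametic copy (undefined
    # inside the insertion, where such copies have no sequence)
    hom_codes = encode(pair.hom[chrom])
    hom_mapped = np.zeros(n, dtype=np.uint8)
    if is_locus_chrom:
        hom_mapped[: locus.start] = hom_codes[: locus.start]
        hom_mapped[locus.start + locus.length :] = hom_codes[locus.start :]
        hom_exists = np.ones(n, dtype=bool)
        hom_exists[locus.start : locus.start + locus.length] = False
    else:
        hom_mapped = hom_codes
        hom_exists = np.ones(n, dtype=bool)

    n_het = sum(1 for ind in members if ind.carrier)
    n_copies = 2 * len(members)
    n_hom = n_copies - n_het

    counts = np.zeros((n, 4), dtype=np.int64)
    if n_hom:
        idx = np.flatnonzero(hom_exists)
        np.add.at(counts, (idx, hom_mapped[idx]), n_hom)
    if n_het:
        np.add.at(counts, (np.arange(n), het_codes), n_het)
    # private SNPs: move one chromosome's base from ref to alt
    for ind in members:
        for copy in (0, 1):
            pos, shift = ind.snps[(chrom, copy)]
            if pos.size == 0:
                continue
            if ind.copy_is_het(copy):
                ref_pos = pos
                refs = het_codes[ref_pos]
            else:
                ref_pos = _map_hom_to_ref(pos, locus) if is_locus_chrom else pos
                refs = hom_mapped[ref_pos]
            alts = (refs + shift) % 4
            np.add.at(counts, (ref_pos, refs), -1)
            np.add.at(counts, (ref_pos, alts), 1)

    n_absent = np.where(hom_exists, 0, n_hom)
    depth = rng.poisson(mean_depth, size=n)
    pvals = np.empty((n, 5), dtype=np.float64)
    pvals[:, :4] = counts / n_copies
    pvals[:, 4] = n_absent / n_copies
    sampled = rng.multinomial(depth, pvals)[:, :4].astype(np.int64)
    if error_rate > 0:
        for b in range(4):
            errs = rng.binomial(sampled[:, b], error_rate)
            sampled[:, b] -= errs
            others = [o for o in range(4) if o != b]
            spread = rng.multinomial(errs, [1 / 3] * 3)
            for j, o in enumerate(others):
                sampled[:, o] += spread[:, j]
    return sampled


def simulate_pool_pileup(
    pop: PopulationSim,
    mean_depth: float = 30.0,
    error_rate: float = DEFAULT_ERROR_RATE,
    seed: int | None = None,
) -> PooledSiteCounts:
    """Per-site nucleotide counts for the phenotypic male and female
    pools, in the coordinate frame of the heterogametic haplotype (so a
    planted insertion has addressable positions).

    At each site the pool's depth is Poisson(mean_depth); each read draws
    one chromosome copy uniformly from the pool, so positions inside a
    sex-limited insertion are covered only in proportion to carrier
    copies (~half the carrier pool's depth) and get no reads from a pool
    without carriers.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    seed = pop.seed if seed is None else seed
    males = [i for i in pop.individuals if i.phenotypic_sex == MALE]
    females = [i for i in pop.individuals if i.phenotypic_sex == FEMALE]
    if not males or not females:
        raise ValueError("both phenotypic sexes must be present")
    carrier_sex = pop.system.carrier_sex
    # streams keyed by carrier status so ZW mirrors XY exactly
    if carrier_sex == FEMALE:
        rng_f = _rng(seed, "pileup-heterogametic")
        rng_m = _rng(seed, "pileup-homogametic")
    else:
        rng_m = _rng(seed, "pileup-heterogametic")
        rng_f = _rng(seed, "pileup-homogametic")

    contigs, positions, male_counts, female_counts, refs = [], [], [], [], []
    lengths: dict[str, int] = {}
    for chrom in pop.haplotypes.het:
        het_seq = pop.haplotypes.het[chrom]
        n = len(het_seq)
        lengths[chrom] = n
        cm = _pool_pileup_chrom(pop, chrom, males, mean_depth, error_rate, rng_m)
        cf = _pool_pileup_chrom(pop, chrom, females, mean_depth, error_rate, rng_f)
        contigs.append(np.full(n, chrom, dtype=object))
        positions.append(np.arange(1, n + 1, dtype=np.int64))
        male_counts.append(cm)
        female_counts.append(cf)
        refs.append(encode(het_seq))
    return PooledSiteCounts(
        np.concatenate(contigs),
        np.concatenate(positions),
        np.concatenate(male_counts),
        np.concatenate(female_counts),
        np.concatenate(refs),
        lengths,
    )


# ---------------------------------------------------------------------------
# k-mer tables


def simulate_kmer_counts(
    pop: PopulationSim,
    k: int = 31,
    depth_per_copy: float | None = DEFAULT_KMER_DEPTH_PER_COPY,
    min_occ: int = 5,
    max_occ: int = 50_000_000,
    seed: int | None = None,
) -> tuple[KmerCounts, KmerCounts]:
    """Canonical k-mer count tables for the male and female pools.

    Genomic k-mer multiplicities are counted over each pool's chromosome
    copy multiset with :func:`sexsignal.kmersex.count_canonical_kmers`;
    when ``depth_per_copy`` is set, observed counts are then drawn as
    Poisson(multiplicity x depth_per_copy) to emulate counting from
    sequencing reads, and the occurrence filter (strictly > min_occ and
    < max_occ) is applied to the observed counts, as a read-based
    counter would. ``depth_per_copy=None`` returns raw multiset counts.
    """
    shortest = min(len(s) for s in pop.haplotypes.hom.values())
    if k > shortest:
        raise ValueError(f"k={k} exceeds shortest sequence length {shortest}")
    seed = pop.seed if seed is None else seed
    carrier_sex = pop.system.carrier_sex

    def pool_table(members: list[Individual], stage: str) -> KmerCounts:
        n_het = sum(1 for ind in members if ind.carrier)
        n_hom = 2 * len(members) - n_het
        seqs, weights = [], []
        for chrom in pop.haplotypes.hom:
            if n_hom:
                seqs.append(pop.haplotypes.hom[chrom])
                weights.append(n_hom)
            if n_het:
                seqs.append(pop.haplotypes.het[chrom])
                weights.append(n_het)
        raw = count_canonical_kmers(seqs, k=k, min_occ=0, max_occ=2**62, weights=weights)
        if depth_per_copy is None:
            keep = (raw.counts > min_occ) & (raw.counts < max_occ)
            return KmerCounts(k, raw.codes[keep], raw.counts[keep])
        rng = _rng(seed, stage)
        observed = rng.poisson(raw.counts * float(depth_per_copy))
        keep = (observed > min_occ) & (observed < max_occ)
        return KmerCounts(k, raw.codes[keep], observed[keep].astype(np.int64))

    males = [i for i in pop.individuals if i.phenotypic_sex == MALE]
    females = [i for i in pop.individuals if i.phenotypic_sex == FEMALE]
    if carrier_sex == FEMALE:
        female_table = pool_table(females, "kmer-heterogametic")
        male_table = pool_table(males, "kmer-homogametic")
    else:
        male_table = pool_table(males, "kmer-heterogametic")
        female_table = pool_table(females, "kmer-homogametic")
    return male_table, female_table


# ---------------------------------------------------------------------------
# FASTA helpers


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
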