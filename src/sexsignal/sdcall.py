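"""Evidence integration: combine marker-association, RAD, pooled-scan
and k-mer results into one sex-determination system call.

The decision rule is deliberately transparent: any single significant,
sex-directed evidence line suffices for an XY or ZW call provided no
significant line points the other way; conflicting directions are never
auto-resolved and yield UNDETERMINED with a conflict flag. Carrier
status of a candidate gene (association testing) is reported separately
from genome-wide signal, so a population where the marker is present
but unlinked remains representable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import kmersex, poolsig, radmarkers, sexassoc, simpop
from .popmap import FEMALE, MALE, PopMap, read_popmap, write_popmap

#: minimum hemizygous 1 kb windows for a coverage evidence line to count
#: as significant (the null rate is well below one window per Mb)
MIN_HEMIZYGOUS_WINDOWS = 3
#: minimum sex-specific SNP count and male:female excess ratio for the
#: pooled SNP scan to count as directed evidence
MIN_SPECIFIC_SNPS = 10
SNP_EXCESS_RATIO = 10.0


@dataclass
class EvidenceLine:
    source: str  # 'assoc', 'rad_markers', 'pool_snps', 'pool_coverage', 'kmers'
    statistic: str
    value: float
    direction: str | None  # 'M', 'F' or None
    significant: bool
    detail: dict = field(default_factory=dict)


@dataclass
class SDReport:
    call: str  # 'XY', 'ZW' or 'UNDETERMINED'
    evidence: list[EvidenceLine]
    locus_size_mb: float | None = None
    locus_size_label: str | None = None
    flags: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "call": self.call,
            "locus_size_mb": self.locus_size_mb,
            "locus_size_label": self.locus_size_label,
            "flags": self.flags,
            "evidence": [asdict(e) for e in self.evidence],
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def classify_sd_system(
    evidence: list[EvidenceLine],
    locus_size: tuple[float, str] | None = None,
) -> SDReport:
    """Apply the one-unopposed-significant-line rule to evidence lines."""
    if not evidence:
        raise ValueError("at least one evidence line is required")
    male_lines = [e for e in evidence if e.significant and e.direction == MALE]
    female_lines = [e for e in evidence if e.significant and e.direction == FEMALE]
    flags: list[str] = []
    if male_lines and female_lines:
        call = "UNDETERMINED"
        flags.append("conflicting male- and female-directed evidence")
    elif male_lines:
        call = "XY"
    elif female_lines:
        call = "ZW"
    else:
        call = "UNDETERMINED"
    for e in evidence:
        if e.source == "assoc" and e.detail.get("carrier_absent"):
            flags.append("carrier absent")
        if (
            e.source == "assoc"
            and not e.significant
            and e.detail.get("carriers", 0) > 0
        ):
            flags.append("marker present but unlinked")
    report = SDReport(call, evidence, flags=sorted(set(flags)))
    if locus_size is not None:
        report.locus_size_mb, report.locus_size_label = locus_size
    return report


# ---------------------------------------------------------------------------
# evidence builders


def association_evidence(
    popmap: PopMap, presence: dict[str, bool], alpha: float = 0.05
) -> EvidenceLine:
    result, table = sexassoc.test_sex_linkage(popmap, presence)
    carriers = table.a + table.c
    direction = None
    if carriers:
        male_rate = table.a / (table.a + table.b) if table.a + table.b else 0.0
        female_rate = table.c / (table.c + table.d) if table.c + table.d else 0.0
        direction = MALE if male_rate > female_rate else FEMALE
    return EvidenceLine(
        source="assoc",
        statistic="yates_chi2_p",
        value=result.p,
        direction=direction,
        significant=(not result.degenerate) and result.p < alpha,
        detail={
            "table": [table.a, table.b, table.c, table.d],
            "chi2": result.chi2,
            "p_display": result.format_p(),
            "carrier_absent": carriers == 0,
            "carriers": carriers,
        },
    )


def rad_evidence(
    table: radmarkers.MarkerDepthTable,
    popmap: PopMap,
    min_depth: int = radmarkers.DEFAULT_MIN_DEPTH,
    alpha: float = radmarkers.DEFAULT_ALPHA,
) -> list[EvidenceLine]:
    sig = radmarkers.significant_markers(table, popmap, min_depth, alpha)
    n_male = sum(1 for s in sig if s.biased_sex == MALE)
    n_female = sum(1 for s in sig if s.biased_sex == FEMALE)
    return [
        EvidenceLine(
            "rad_markers",
            "n_significant_male_markers",
            n_male,
            MALE,
            n_male > 0,
            {"markers": [s.marker_id for s in sig if s.biased_sex == MALE]},
        ),
        EvidenceLine(
            "rad_markers",
            "n_significant_female_markers",
            n_female,
            FEMALE,
            n_female > 0,
            {"markers": [s.marker_id for s in sig if s.biased_sex == FEMALE]},
        ),
    ]


def pool_evidence(
    sites: poolsig.PooledSiteCounts,
    params: poolsig.SnpParams = poolsig.SnpParams(),
    window_size: int = 50_000,
) -> list[EvidenceLine]:
    windows = poolsig.window_scan(
        sites, window_size=window_size, params=params, mode="tiled"
    )
    n_male_snps = int(windows["male_specific_snps"].sum())
    n_female_snps = int(windows["female_specific_snps"].sum())
    snp_dir = None
    snp_sig = False
    if n_male_snps >= MIN_SPECIFIC_SNPS and n_male_snps >= SNP_EXCESS_RATIO * max(
        n_female_snps, 1
    ):
        snp_dir, snp_sig = MALE, True
    elif n_female_snps >= MIN_SPECIFIC_SNPS and n_female_snps >= SNP_EXCESS_RATIO * max(
        n_male_snps, 1
    ):
        snp_dir, snp_sig = FEMALE, True
    lines = [
        EvidenceLine(
            "pool_snps",
            "sex_specific_snps",
            max(n_male_snps, n_female_snps),
            snp_dir,
            snp_sig,
            {"male_specific": n_male_snps, "female_specific": n_female_snps},
        )
    ]
    # hemizygous coverage: male-limited (Y) then female-limited (W)
    for label, direction, data in (
        ("y_specific_windows", MALE, sites),
        ("w_specific_windows", FEMALE, sites.swapped()),
    ):
        try:
            flagged, regions = poolsig.detect_hemizygous_windows(data)
            n_flagged = int(flagged["flagged"].sum())
        except ValueError:
            n_flagged, regions = 0, []
        lines.append(
            EvidenceLine(
                "pool_coverage",
                label,
                n_flagged,
                direction,
                n_flagged >= MIN_HEMIZYGOUS_WINDOWS,
                {"regions": [[c, int(s), int(e)] for c, s, e in regions]},
            )
        )
    return lines


def kmer_evidence(
    male_table: kmersex.KmerCounts,
    female_table: kmersex.KmerCounts,
    high: int = kmersex.DEFAULT_HIGH,
    low: int = kmersex.DEFAULT_LOW,
) -> EvidenceLine:
    male_specific, female_specific = kmersex.merge_and_filter(
        male_table, female_table, high, low
    )
    call = kmersex.infer_heterogamety(len(male_specific), len(female_specific))
    direction = {"XY": MALE, "ZW": FEMALE}.get(call.system)
    return EvidenceLine(
        "kmers",
        "sex_specific_kmer_ratio",
        call.ratio if call.ratio != float("inf") else -1.0,
        direction,
        call.system != "UNDETERMINED",
        {
            "n_male_specific": call.n_male_specific,
            "n_female_specific": call.n_female_specific,
            "ratio_display": call.ratio_display,
            "call": call.system,
        },
    )


# ---------------------------------------------------------------------------
# pipeline


def _simulate_inputs(sim_cfg: dict, seed: int, outdir: Path):
    system = simpop.SDSystem(sim_cfg.get("system", "NONE"))
    n_chrom = int(sim_cfg.get("n_chrom", 1))
    chrom_length = int(sim_cfg.get("chrom_length", 1_000_000))
    enzyme = sim_cfg.get("enzyme_site", simpop.DEFAULT_ENZYME_SITE)
    reference = simpop.simulate_reference(n_chrom, chrom_length, seed)
    locus_cfg = sim_cfg.get("locus", {})
    spec = simpop.SexLocusSpec(
        system=system,
        chrom=locus_cfg.get("chrom", "chr1" if system != simpop.SDSystem.NONE else ""),
        start=int(locus_cfg.get("start", chrom_length // 2))
        if system != simpop.SDSystem.NONE
        else 0,
        length=int(locus_cfg.get("length", 0)),
        snp_divergence=float(locus_cfg.get("snp_divergence", 0.0)),
    )
    pair = simpop.plant_sex_locus(
        reference,
        spec,
        seed,
        enzyme_site=enzyme,
        planted_motifs=int(sim_cfg.get("planted_motifs", 3))
        if system.is_insertion
        else 0,
    )
    pop = simpop.simulate_individuals(
        pair,
        int(sim_cfg.get("n_males", 20)),
        int(sim_cfg.get("n_females", 20)),
        theta=float(sim_cfg.get("theta", simpop.DEFAULT_THETA)),
        sex_reversal_rate=float(sim_cfg.get("sex_reversal_rate", 0.0)),
        seed=seed,
    )
    write_popmap(pop.popmap, outdir / "popmap.tsv")
    reads = simpop.simulate_rad_reads(
        pop,
        enzyme_site=enzyme,
        read_length=int(sim_cfg.get("read_length", 80)),
        mean_depth=float(sim_cfg.get("rad_depth", 30)),
        error_rate=float(sim_cfg.get("error_rate", simpop.DEFAULT_ERROR_RATE)),
    )
    sites = simpop.simulate_pool_pileup(
        pop,
        mean_depth=float(sim_cfg.get("pool_depth", 30)),
        error_rate=float(sim_cfg.get("error_rate", simpop.DEFAULT_ERROR_RATE)),
    )
    kmer_m, kmer_f = simpop.simulate_kmer_counts(
        pop, k=int(sim_cfg.get("k", 31))
    )
    density = radmarkers.marker_density(
        [(n, pair.hom[n]) for n in pair.hom], enzyme
    )
    return pop.popmap, reads, sites, (kmer_m, kmer_f), density


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> SDReport:
    """Execute the configured analyses and write a JSON report plus all
    intermediate tables to ``outdir``. Deterministic for a fixed config
    and seed (no timestamps in outputs)."""
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    analyses = config.get("analyses", ["rad", "pool", "kmer"])

    popmap = None
    reads = None
    sites = None
    kmer_tables = None
    density = config.get("marker_density")
    presence = None

    if "simulate" in config:
        popmap, reads, sites, kmer_tables, density = _simulate_inputs(
            config["simulate"], seed, outdir
        )
    else:
        if "popmap" in config:
            popmap = read_popmap(config["popmap"])
        if "pileup" in config:
            sites = poolsig.read_pileup(config["pileup"])
        if "kmer_male" in config and "kmer_female" in config:
            kmer_tables = (
                kmersex.read_kmer_table(config["kmer_male"]),
                kmersex.read_kmer_table(config["kmer_female"]),
            )
        if "presence" in config:
            presence = sexassoc.read_presence(config["presence"])

    evidence: list[EvidenceLine] = []
    locus_size = None

    if presence is not None:
        if popmap is None:
            raise ValueError("association analysis requires a popmap")
        evidence.append(association_evidence(popmap, presence))

    marker_table = None
    if "marker_table" in config:
        marker_table = radmarkers.read_marker_table(config["marker_table"])
    elif reads is not None:
        marker_table = radmarkers.build_marker_table(reads, popmap)
    if "rad" in analyses and marker_table is not None:
        if popmap is None:
            raise ValueError("RAD analysis requires a popmap")
        min_depth = int(config.get("min_depth", radmarkers.DEFAULT_MIN_DEPTH))
        radmarkers.write_marker_table(marker_table, outdir / "markers.tsv")
        dist = radmarkers.marker_distribution(marker_table, popmap, min_depth)
        dist.to_frame().to_csv(outdir / "marker_distribution.tsv", sep="\t", index=False)
        sig = radmarkers.significant_markers(marker_table, popmap, min_depth)
        radmarkers.write_significant_markers(sig, outdir / "significant_markers.tsv")
        evidence.extend(rad_evidence(marker_table, popmap, min_depth))
        if density:
            n_sig = len(sig)
            locus_size = radmarkers.estimate_locus_size(n_sig, float(density))

    if "pool" in analyses and sites is not None:
        params = poolsig.SnpParams(
            freq_het=float(config.get("freq_het", 0.5)),
            range_het=float(config.get("range_het", 0.15)),
            freq_hom=float(config.get("freq_hom", 1.0)),
            range_hom=float(config.get("range_hom", 0.05)),
            min_depth=int(config.get("pool_min_depth", 1)),
        )
        window_size = int(config.get("window_size", 50_000))
        windows = poolsig.window_scan(sites, window_size=window_size, params=params)
        windows.to_csv(outdir / "pool_windows.tsv", sep="\t", index=False)
        lines = pool_evidence(sites, params, window_size)
        for line in lines:
            if line.source == "pool_coverage" and line.detail["regions"]:
                tag = "y" if line.direction == MALE else "w"
                poolsig.write_regions_bed(
                    [tuple(r) for r in line.detail["regions"]],
                    outdir / f"{tag}_specific_regions.bed",
                )
        evidence.extend(lines)

    if "kmer" in analyses and kmer_tables is not None:
        evidence.append(kmer_evidence(*kmer_tables))

    if not evidence:
        raise ValueError("no analyses produced evidence; check config inputs")
    report = classify_sd_system(evidence, locus_size)
    (outdir / "report.json").write_text(report.to_json() + "\n")
    return report
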