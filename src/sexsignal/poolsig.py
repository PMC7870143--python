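"""Pooled-sequencing sex-contrast scan.

Input is a per-site nucleotide count table with one male and one female
pool (the standard pileup-derived "pool pileup" layout). Four analyses are
provided:

* per-site classification into male-specific / female-specific SNPs — a
  site heterozygous-like in one sex's pool (some allele at frequency
  ``freq_het ± range_het``, at least two alleles seen, and carrying an
  allele absent from the other pool's consensus) while the other pool is
  fixed (major-allele frequency ``>= freq_hom - range_hom``);
* per-site FST between pools, using the heterozygosity-ratio estimator
  FST = (H_T - H_S) / H_T with H_T from the mean of the two pool allele
  frequencies and H_S the mean within-pool expected heterozygosity;
* window aggregation (tiled non-overlapping windows, or sliding windows
  advanced by an output resolution) of SNP counts, depths and FST;
* detection of hemizygous (Y- or W-specific) regions as 1 kb windows with
  almost no reads from the homogametic sex and roughly half-coverage in
  the heterogametic sex — a hemizygous insertion is carried by one of the
  two chromosome copies of carrier individuals only.

All frequency thresholds are inclusive; the only strict comparison is the
``< 3`` female-coverage cutoff in hemizygous-window detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._dna import BASES

#: slack for inclusive frequency-boundary comparisons (counts are exact
#: integers but frequencies are binary floats; 13/20 must test equal to
#: 0.5 + 0.15)
_EPS = 1e-9

SITE_NONE = 0
SITE_MALE_SPECIFIC = 1
SITE_FEMALE_SPECIFIC = 2
SITE_UNCOVERED = -1

_CLASS_NAMES = {
    SITE_NONE: "NONE",
    SITE_MALE_SPECIFIC: "MALE_SPECIFIC",
    SITE_FEMALE_SPECIFIC: "FEMALE_SPECIFIC",
    SITE_UNCOVERED: "UNCOVERED",
}


@dataclass(frozen=True)
class SnpParams:
    """Thresholds for pool-based sex-specific SNP classification.

    freq_het/range_het: target frequency window for the heterozygous-like
    pool (an X/Y-differentiated site sits at ~0.5 in the heterogametic
    pool). freq_hom/range_hom: minimum major-allele frequency for the
    fixed pool. min_depth: minimum per-pool depth for a site to count as
    covered.
    """

    freq_het: float = 0.5
    range_het: float = 0.15
    freq_hom: float = 1.0
    range_hom: float = 0.05
    min_depth: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.freq_het <= 1:
            raise ValueError("freq_het must be in (0, 1]")
        if self.range_het < 0 or self.range_hom < 0:
            raise ValueError("ranges must be non-negative")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass
class PooledSiteCounts:
    """Per-site A/C/G/T counts for the male and female pools.

    Positions are 1-based and strictly increasing within each contig.
    ``ref`` optionally stores the reference base code per site.
    """

    contigs: np.ndarray  # object array of contig IDs, grouped
    pos: np.ndarray  # int64, 1-based
    male: np.ndarray  # (n, 4) int64 A,C,G,T
    female: np.ndarray  # (n, 4) int64
    ref: np.ndarray | None = None  # uint8 base codes
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.pos)
        if not (len(self.contigs) == n and len(self.male) == n == len(self.female)):
            raise ValueError("pooled count arrays must have equal length")
        if (self.male < 0).any() or (self.female < 0).any():
            raise ValueError("nucleotide counts must be non-negative")
        for contig in dict.fromkeys(self.contigs):
            p = self.pos[self.contigs == contig]
            if p.size > 1 and not (np.diff(p) > 0).all():
                raise ValueError(
                    f"positions not strictly increasing on contig {contig!r}"
                )

    def __len__(self) -> int:
        return len(self.pos)

    def length_of(self, contig: str) -> int:
        if contig in self.contig_lengths:
            return self.contig_lengths[contig]
        return int(self.pos[self.contigs == contig].max())

    def swapped(self) -> "PooledSiteCounts":
        """Pool-label swap (polarity-mirror helper)."""
        return PooledSiteCounts(
            self.contigs,
            self.pos,
            self.female.copy(),
            self.male.copy(),
            self.ref,
            dict(self.contig_lengths),
        )


def _pool_stats(counts: np.ndarray):
    """totals, frequencies, major index, major freq, allele count."""
    totals = counts.sum(axis=1)
    safe = np.maximum(totals, 1)
    freqs = counts / safe[:, None]
    major = counts.argmax(axis=1)
    major_freq = freqs[np.arange(len(counts)), major]
    n_alleles = (counts > 0).sum(axis=1)
    return totals, freqs, major, major_freq, n_alleles


def _het_like(freqs, n_alleles, other_major, params: SnpParams) -> np.ndarray:
    """Pool shows an allele in the het window that differs from the other
    pool's major allele, with at least two alleles observed."""
    lo = params.freq_het - params.range_het - _EPS
    hi = params.freq_het + params.range_het + _EPS
    in_window = (freqs >= lo) & (freqs <= hi)
    differs = np.arange(4)[None, :] != other_major[:, None]
    return (n_alleles >= 2) & (in_window & differs).any(axis=1)


def classify_sites(
    sites: PooledSiteCounts, params: SnpParams = SnpParams()
) -> np.ndarray:
    """Vectorised sex-specific SNP classification.

    Returns an int8 array: 1 male-specific, 2 female-specific, 0 neither,
    -1 uncovered (either pool below min_depth).
    """
    tm, fm, majm, majfm, nm = _pool_stats(sites.male)
    tf, ff, majf, majff, nf = _pool_stats(sites.female)
    covered = (tm >= params.min_depth) & (tf >= params.min_depth)
    hom_thresh = params.freq_hom - params.range_hom - _EPS
    male_hom = majfm >= hom_thresh
    female_hom = majff >= hom_thresh
    male_specific = _het_like(fm, nm, majf, params) & female_hom
    female_specific = _het_like(ff, nf, majm, params) & male_hom
    out = np.zeros(len(sites), dtype=np.int8)
    out[male_specific & ~female_specific] = SITE_MALE_SPECIFIC
    out[female_specific & ~male_specific] = SITE_FEMALE_SPECIFIC
    out[~covered] = SITE_UNCOVERED
    return out


def classify_site(
    male_counts, female_counts, params: SnpParams = SnpParams()
) -> str:
    """Classify a single site; returns 'MALE_SPECIFIC', 'FEMALE_SPECIFIC',
    'NONE' or 'UNCOVERED'."""
    sites = PooledSiteCounts(
        np.array(["_"], dtype=object),
        np.array([1]),
        np.asarray([male_counts], dtype=np.int64),
        np.asarray([female_counts], dtype=np.int64),
    )
    return _CLASS_NAMES[int(classify_sites(sites, params)[0])]


def site_fst_array(
    sites: PooledSiteCounts, params: SnpParams = SnpParams()
) -> np.ndarray:
    """Per-site FST between pools; NaN where a pool is uncovered."""
    tm = sites.male.sum(axis=1)
    tf = sites.female.sum(axis=1)
    covered = (tm >= params.min_depth) & (tf >= params.min_depth)
    fm = sites.male / np.maximum(tm, 1)[:, None]
    ff = sites.female / np.maximum(tf, 1)[:, None]
    hs = 0.5 * ((1 - (fm**2).sum(axis=1)) + (1 - (ff**2).sum(axis=1)))
    pbar = 0.5 * (fm + ff)
    ht = 1 - (pbar**2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(ht > 0, (ht - hs) / np.where(ht > 0, ht, 1), 0.0)
    fst = np.clip(fst, 0.0, 1.0)
    fst[~covered] = np.nan
    return fst


def site_fst(male_counts, female_counts) -> float:
    """FST between pools at a single site (0 when both pools are fixed
    for the same allele, 1 for a fixed difference)."""
    sites = PooledSiteCounts(
        np.array(["_"], dtype=object),
        np.array([1]),
        np.asarray([male_counts], dtype=np.int64),
        np.asarray([female_counts], dtype=np.int64),
    )
    val = site_fst_array(sites)[0]
    if np.isnan(val):
        raise ValueError("both pools must reach min_depth")
    return float(val)


def _window_starts(length: int, window_size: int, step: int) -> np.ndarray:
    if length <= window_size:
        return np.array([0], dtype=np.int64)
    return np.arange(0, length - window_size + step, step, dtype=np.int64)


def window_scan(
    sites: PooledSiteCounts,
    window_size: int = 50_000,
    output_resolution: int = 1000,
    params: SnpParams = SnpParams(),
    mode: str = "tiled",
) -> pd.DataFrame:
    """Aggregate per-site statistics into genomic windows.

    ``tiled`` mode uses non-overlapping windows of ``window_size``;
    ``sliding`` advances a ``window_size`` window by ``output_resolution``.
    Columns: contig, start, end (0-based half-open), male_specific_snps,
    female_specific_snps, fst (mean site FST over jointly covered sites),
    male_depth / female_depth (per-base mean over the window),
    male_rel_depth (ratio to the genome-wide male mean over male-covered
    sites).
    """
    if window_size < output_resolution:
        raise ValueError("window_size must be >= output_resolution")
    if mode not in ("tiled", "sliding"):
        raise ValueError(f"unknown mode {mode!r}")
    cls = classify_sites(sites, params)
    fst = site_fst_array(sites, params)
    tm = sites.male.sum(axis=1)
    tf = sites.female.sum(axis=1)
    male_covered = tm >= 1
    genome_male_mean = float(tm[male_covered].mean()) if male_covered.any() else 0.0

    step = window_size if mode == "tiled" else output_resolution
    rows = []
    for contig in dict.fromkeys(sites.contigs):
        sel = sites.contigs == contig
        pos0 = sites.pos[sel] - 1  # 0-based
        c_male = np.cumsum(np.concatenate([[0], (cls[sel] == SITE_MALE_SPECIFIC)]))
        c_female = np.cumsum(np.concatenate([[0], (cls[sel] == SITE_FEMALE_SPECIFIC)]))
        fst_c = np.nan_to_num(fst[sel], nan=0.0)
        c_fst = np.cumsum(np.concatenate([[0.0], fst_c]))
        c_cov = np.cumsum(np.concatenate([[0], ~np.isnan(fst[sel])]))
        c_tm = np.cumsum(np.concatenate([[0], tm[sel]]))
        c_tf = np.cumsum(np.concatenate([[0], tf[sel]]))
        length = sites.length_of(contig)
        starts = _window_starts(length, window_size, step)
        ends = np.minimum(starts + window_size, length)
        lo = np.searchsorted(pos0, starts, side="left")
        hi = np.searchsorted(pos0, ends, side="left")
        n_cov = c_cov[hi] - c_cov[lo]
        sum_fst = c_fst[hi] - c_fst[lo]
        span = np.maximum(ends - starts, 1)
        for i in range(len(starts)):
            rows.append(
                (
                    contig,
                    int(starts[i]),
                    int(ends[i]),
                    int(c_male[hi[i]] - c_male[lo[i]]),
                    int(c_female[hi[i]] - c_female[lo[i]]),
                    float(sum_fst[i] / n_cov[i]) if n_cov[i] else 0.0,
                    float((c_tm[hi[i]] - c_tm[lo[i]]) / span[i]),
                    float((c_tf[hi[i]] - c_tf[lo[i]]) / span[i]),
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "contig",
            "start",
            "end",
            "male_specific_snps",
            "female_specific_snps",
            "fst",
            "male_depth",
            "female_depth",
        ],
    )
    df["male_rel_depth"] = (
        df["male_depth"] / genome_male_mean if genome_male_mean > 0 else np.nan
    )
    return df


def detect_hemizygous_windows(
    sites: PooledSiteCounts,
    window: int = 1000,
    female_max_reads_per_kb: float = 3.0,
    male_rel_depth_range: tuple[float, float] = (0.4, 0.6),
) -> tuple[pd.DataFrame, list[tuple[str, int, int]]]:
    """Scan for Y/W-specific windows by sex-contrasted coverage.

    A window is flagged iff its female coverage is strictly below
    ``female_max_reads_per_kb`` (per-base mean depth over the window,
    scaled to the window span) and its male depth relative to the
    genome-wide male mean lies inclusively within
    ``male_rel_depth_range`` — the half-coverage signature of a sequence
    present on only one of the carrier sex's two chromosome copies.

    Returns the per-window table and the merged flagged regions as
    0-based half-open (contig, start, end) intervals.
    """
    tm = sites.male.sum(axis=1)
    male_covered = tm >= 1
    if not male_covered.any() or tm[male_covered].mean() == 0:
        raise ValueError("no male-pool coverage; cannot establish depth baseline")
    df = window_scan(sites, window_size=window, output_resolution=window, mode="tiled")
    lo, hi = male_rel_depth_range
    # with 1 kb windows, per-base mean depth is the "reads per kb" statistic
    female_per_kb = df["female_depth"]
    df = df.copy()
    df["flagged"] = (
        (female_per_kb < female_max_reads_per_kb)
        & (df["male_rel_depth"] >= lo - _EPS)
        & (df["male_rel_depth"] <= hi + _EPS)
    )
    regions: list[tuple[str, int, int]] = []
    for contig, sub in df[df["flagged"]].groupby("contig", sort=False):
        sub = sub.sort_values("start")
        cur_start = cur_end = None
        for _, row in sub.iterrows():
            if cur_end is not None and row["start"] == cur_end:
                cur_end = int(row["end"])
            else:
                if cur_start is not None:
                    regions.append((contig, cur_start, cur_end))
                cur_start, cur_end = int(row["start"]), int(row["end"])
        if cur_start is not None:
            regions.append((contig, cur_start, cur_end))
    return df, regions


def write_regions_bed(regions, path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig, start, end in regions:
            fh.write(f"{contig}\t{start}\t{end}\n")


def write_pileup(sites: PooledSiteCounts, path: str | Path) -> None:
    """Write the pileup-count TSV:
    ``contig<TAB>pos<TAB>ref<TAB>A_m,C_m,G_m,T_m<TAB>A_f,C_f,G_f,T_f``."""
    refs = (
        [BASES[c] if c < 4 else "N" for c in sites.ref]
        if sites.ref is not None
        else ["N"] * len(sites)
    )
    with open(path, "w") as fh:
        for i in range(len(sites)):
            m = ",".join(str(x) for x in sites.male[i])
            f = ",".join(str(x) for x in sites.female[i])
            fh.write(f"{sites.contigs[i]}\t{sites.pos[i]}\t{refs[i]}\t{m}\t{f}\n")


def read_pileup(path: str | Path) -> PooledSiteCounts:
    df = pd.read_csv(
        path,
        sep="\t",
        names=["contig", "pos", "ref", "male", "female"],
        dtype={"contig": str},
        comment="#",
    )
    male = np.array(
        [[int(x) for x in s.split(",")] for s in df["male"]], dtype=np.int64
    )
    female = np.array(
        [[int(x) for x in s.split(",")] for s in df["female"]], dtype=np.int64
    )
    base_codes = {"A": 0, "C": 1, "G": 2, "T": 3}
    ref = np.array([base_codes.get(b, 4) for b in df["ref"]], dtype=np.uint8)
    return PooledSiteCounts(
        df["contig"].to_numpy(dtype=object),
        df["pos"].to_numpy(dtype=np.int64),
        male,
        female,
        ref,
    )
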