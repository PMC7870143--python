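"""RAD-seq presence/absence marker analysis.

A marker is a distinct exact read sequence (non-polymorphic marker
convention: sequence variants are never merged). The marker depth table
counts identical reads per individual; presence is depth >= a minimum
depth threshold. The marker-by-sex tile distribution counts, for each
cell (m, f), the markers present in exactly m males and f females, tests
every cell with the Yates-corrected chi-square against the sex margins,
and applies a Bonferroni correction over all (M+1)(F+1) possible tiles.

Because single-digest RAD yields one marker on each flank of a cut site,
the number of significant markers together with the genome's
restriction-site density gives a rough physical size for the
non-recombining sex locus: size ~ n_markers / (2 * sites_per_Mb).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .popmap import PopMap
from .sexassoc import PresenceTable, yates_chi2

DEFAULT_MIN_DEPTH = 10
DEFAULT_ALPHA = 0.05

#: reporting convention: loci below this size are labelled "small"
SMALL_LOCUS_MB = 0.5


@dataclass
class MarkerDepthTable:
    """Markers x individuals depth matrix.

    ``sequences`` holds the distinct fixed-length marker sequences (row
    order), ``individuals`` the column order, ``depths`` the integer
    depth matrix.
    """

    sequences: list[str]
    individuals: list[str]
    depths: np.ndarray  # (n_markers, n_individuals) int64
    read_length: int

    def __post_init__(self) -> None:
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("marker sequences must be distinct")
        if any(len(s) != self.read_length for s in self.sequences):
            raise ValueError("marker sequences must all have read_length")
        if (self.depths < 0).any():
            raise ValueError("depths must be non-negative")

    @property
    def n_markers(self) -> int:
        return len(self.sequences)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.depths, columns=self.individuals)
        df.insert(0, "sequence", self.sequences)
        df.insert(0, "id", [f"M{i}" for i in range(self.n_markers)])
        return df


@dataclass
class DistributionMatrix:
    """Tile distribution of markers shared between m males and f females."""

    counts: np.ndarray  # (M+1, F+1) int64
    p_values: np.ndarray  # (M+1, F+1) float
    significant: np.ndarray  # (M+1, F+1) bool
    n_males: int
    n_females: int
    min_depth: int
    alpha: float

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / ((self.n_males + 1) * (self.n_females + 1))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in range(self.n_males + 1):
            for f in range(self.n_females + 1):
                rows.append(
                    (
                        m,
                        f,
                        int(self.counts[m, f]),
                        float(self.p_values[m, f]),
                        bool(self.significant[m, f]),
                    )
                )
        return pd.DataFrame(
            rows, columns=["n_males", "n_females", "n_markers", "p", "significant"]
        )


def build_marker_table(
    reads_by_individual: dict[str, list[str]], popmap: PopMap
) -> MarkerDepthTable:
    """Collapse per-individual read sets into a marker depth table.

    Every popmap individual must have a (possibly empty) read set; all
    reads must share one length.
    """
    missing = sorted(set(popmap) - set(reads_by_individual))
    if missing:
        raise KeyError(f"no read set for individuals: {', '.join(missing)}")
    lengths = {len(r) for reads in reads_by_individual.values() for r in reads}
    if len(lengths) > 1:
        raise ValueError(f"mixed read lengths: {sorted(lengths)}")
    read_length = lengths.pop() if lengths else 0
    individuals = list(popmap)
    marker_index: dict[str, int] = {}
    cells: dict[tuple[int, int], int] = {}
    for col, ind in enumerate(individuals):
        for read in reads_by_individual.get(ind, []):
            row = marker_index.setdefault(read, len(marker_index))
            cells[(row, col)] = cells.get((row, col), 0) + 1
    # deterministic row order: lexicographic by sequence
    seqs = sorted(marker_index)
    remap = {marker_index[s]: i for i, s in enumerate(seqs)}
    depths = np.zeros((len(seqs), len(individuals)), dtype=np.int64)
    for (row, col), depth in cells.items():
        depths[remap[row], col] = depth
    return MarkerDepthTable(seqs, individuals, depths, read_length)


def _presence_counts(table: MarkerDepthTable, popmap: PopMap, min_depth: int):
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    male_cols = [i for i, ind in enumerate(table.individuals) if popmap[ind] == "M"]
    female_cols = [i for i, ind in enumerate(table.individuals) if popmap[ind] == "F"]
    present = table.depths >= min_depth
    m = present[:, male_cols].sum(axis=1)
    f = present[:, female_cols].sum(axis=1)
    return m, f, len(male_cols), len(female_cols)


def _tile_pvalues(M: int, F: int) -> np.ndarray:
    p = np.ones((M + 1, F + 1))
    for m in range(M + 1):
        for f in range(F + 1):
            p[m, f] = yates_chi2(PresenceTable(m, M - m, f, F - f)).p
    return p


def marker_distribution(
    table: MarkerDepthTable,
    popmap: PopMap,
    min_depth: int = DEFAULT_MIN_DEPTH,
    alpha: float = DEFAULT_ALPHA,
) -> DistributionMatrix:
    """Tile distribution of markers by number of males/females carrying
    them (depth >= min_depth), with per-tile chi-square p-values and a
    Bonferroni mask over all possible tiles."""
    m, f, M, F = _presence_counts(table, popmap, min_depth)
    if M == 0 or F == 0:
        raise ValueError("both sexes must be present in the popmap")
    counts = np.zeros((M + 1, F + 1), dtype=np.int64)
    keep = (m > 0) | (f > 0)
    np.add.at(counts, (m[keep], f[keep]), 1)
    p = _tile_pvalues(M, F)
    significant = p < alpha / ((M + 1) * (F + 1))
    return DistributionMatrix(counts, p, significant, M, F, min_depth, alpha)


@dataclass(frozen=True)
class SignificantMarker:
    marker_id: str
    sequence: str
    n_males: int
    n_females: int
    p: float
    biased_sex: str  # "M" or "F"


def significant_markers(
    table: MarkerDepthTable,
    popmap: PopMap,
    min_depth: int = DEFAULT_MIN_DEPTH,
    alpha: float = DEFAULT_ALPHA,
) -> list[SignificantMarker]:
    """Markers whose (m, f) presence cell passes the Bonferroni-corrected
    chi-square test, labelled by the sex they are biased toward, ordered
    by (p, marker ID)."""
    m, f, M, F = _presence_counts(table, popmap, min_depth)
    if M == 0 or F == 0:
        raise ValueError("both sexes must be present in the popmap")
    p = _tile_pvalues(M, F)
    threshold = alpha / ((M + 1) * (F + 1))
    ids = [f"M{i}" for i in range(table.n_markers)]
    out = []
    for i in range(table.n_markers):
        pv = p[m[i], f[i]]
        if pv < threshold:
            biased = "M" if m[i] / M > f[i] / F else "F"
            out.append(
                SignificantMarker(
                    ids[i], table.sequences[i], int(m[i]), int(f[i]), float(pv), biased
                )
            )
    out.sort(key=lambda r: (r.p, r.marker_id))
    return out


def marker_density(references, enzyme_site: str) -> float:
    """Restriction-site density in sites per Mb.

    ``references`` is an iterable of (name, sequence) pairs or plain
    sequences. Occurrences are counted on the forward strand with overlap
    allowed, so a palindromic motif is counted once per position.
    """
    if not enzyme_site:
        raise ValueError("enzyme motif must be non-empty")
    total_len = 0
    total_sites = 0
    n_records = 0
    for rec in references:
        seq = rec[1] if isinstance(rec, tuple) else str(rec)
        n_records += 1
        total_len += len(seq)
        start = 0
        while True:
            idx = seq.find(enzyme_site, start)
            if idx < 0:
                break
            total_sites += 1
            start = idx + 1
    if n_records == 0 or total_len == 0:
        raise ValueError("reference must be non-empty")
    return total_sites / (total_len / 1e6)


def estimate_locus_size(n_significant: int, density: float) -> tuple[float, str]:
    """Heuristic sex-locus size from significant marker count and
    restriction-site density (two markers per cut site, one per flank).

    Returns (size in Mb, 'small'|'large'); the 0.5 Mb cutoff is a
    reporting convention only.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    if n_significant < 0:
        raise ValueError("marker count must be non-negative")
    size_mb = n_significant / (2.0 * density)
    return size_mb, "small" if size_mb < SMALL_LOCUS_MB else "large"


def write_marker_table(table: MarkerDepthTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_marker_table(path: str | Path) -> MarkerDepthTable:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sequence": str})
    individuals = [c for c in df.columns if c not in ("id", "sequence")]
    seqs = df["sequence"].tolist()
    depths = df[individuals].to_numpy(dtype=np.int64)
    read_length = len(seqs[0]) if seqs else 0
    return MarkerDepthTable(seqs, individuals, depths, read_length)


def write_significant_markers(markers, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsequence\tn_males\tn_females\tp\tbiased_sex\n")
        for rec in markers:
            fh.write(
                f"{rec.marker_id}\t{rec.sequence}\t{rec.n_males}\t"
                f"{rec.n_females}\t{rec.p:.6g}\t{rec.biased_sex}\n"
            )
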