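"""Sex-biased k-mer analysis and heterogamety inference.

Canonical k-mers (the lexicographic minimum of a k-mer and its reverse
complement) are counted per sex pool, the two tables are merged, and
k-mers strongly over-represented in one pool and nearly absent from the
other are flagged as sex-biased. A strong excess of one sex's specific
k-mers indicates that sex carries genomic sequence the other lacks —
i.e. it is the heterogametic sex (XY if male, ZW if female).

Counts are stored as sorted uint64 2-bit k-mer codes with parallel count
arrays, so genome-scale tables stay compact; the table still behaves as a
read-only mapping from k-mer string to count for interactive use.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterator, Mapping
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._dna import BASES, encode

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

DEFAULT_K = 31
DEFAULT_MIN_OCC = 5
DEFAULT_MAX_OCC = 50_000_000
DEFAULT_HIGH = 25
DEFAULT_LOW = 5


def _window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """2-bit pack every k-window of a code array; windows with non-ACGT
    symbols are dropped."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    m = n - k + 1
    vals = np.zeros(m, dtype=np.uint64)
    clean = np.where(codes < 4, codes, 0).astype(np.uint64)
    for j in range(k):
        vals = (vals << np.uint64(2)) | clean[j : j + m]
    bad = (codes >= 4).astype(np.int32)
    bad_in_window = np.convolve(bad, np.ones(k, dtype=np.int32), mode="valid")
    return vals[bad_in_window == 0]


def _canonical_codes(seq: str | np.ndarray, k: int) -> np.ndarray:
    codes = encode(seq) if isinstance(seq, str) else np.asarray(seq, dtype=np.uint8)
    fwd = _window_codes(codes, k)
    if fwd.size == 0:
        return fwd
    rev = _window_codes(_COMP[codes][::-1], k)[::-1]
    return np.minimum(fwd, rev)


def kmer_to_code(kmer: str) -> int:
    codes = encode(kmer)
    if (codes >= 4).any():
        raise ValueError(f"non-ACGT symbol in k-mer {kmer!r}")
    val = 0
    for c in codes:
        val = (val << 2) | int(c)
    return val


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(BASES[(code >> shift) & 3])
    return "".join(out)


def canonicalize(kmer: str) -> str:
    k = len(kmer)
    canon = _canonical_codes(kmer, k)
    if canon.size != 1:
        raise ValueError(f"cannot canonicalize {kmer!r}")
    return code_to_kmer(int(canon[0]), k)


@dataclass(frozen=True)
class KmerCounts(Mapping):
    """Canonical k-mer count table backed by sorted code arrays."""

    k: int
    codes: np.ndarray  # uint64, strictly increasing
    counts: np.ndarray  # int64, parallel to codes

    def __len__(self) -> int:
        return int(self.codes.size)

    def __iter__(self) -> Iterator[str]:
        for code in self.codes:
            yield code_to_kmer(int(code), self.k)

    def __getitem__(self, kmer: str) -> int:
        code = kmer_to_code(canonicalize(kmer))
        idx = int(np.searchsorted(self.codes, np.uint64(code)))
        if idx < len(self.codes) and self.codes[idx] == code:
            return int(self.counts[idx])
        raise KeyError(kmer)

    def to_dict(self) -> dict[str, int]:
        return dict(self.items())


def count_canonical_kmers(
    sequences,
    k: int = DEFAULT_K,
    min_occ: int = DEFAULT_MIN_OCC,
    max_occ: int = DEFAULT_MAX_OCC,
    weights=None,
) -> KmerCounts:
    """Count canonical k-mers over a collection of sequences.

    Retains k-mers with total occurrence strictly greater than ``min_occ``
    and strictly less than ``max_occ`` (pass ``min_occ=0`` to keep
    everything). ``weights`` optionally gives a multiplicity per sequence,
    so a haplotype carried by w chromosomes is counted once and scaled.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    sequences = list(sequences)
    if weights is None:
        weights = [1] * len(sequences)
    elif len(weights) != len(sequences):
        raise ValueError("weights must align with sequences")
    chunks: list[np.ndarray] = []
    wchunks: list[np.ndarray] = []
    too_short = 0
    for seq, w in zip(sequences, weights):
        canon = _canonical_codes(seq, k)
        if canon.size == 0:
            too_short += 1
            continue
        codes, counts = np.unique(canon, return_counts=True)
        chunks.append(codes)
        wchunks.append(counts.astype(np.int64) * int(w))
    if not chunks:
        if sequences and too_short == len(sequences):
            warnings.warn(f"k={k} exceeds every sequence length; empty table")
        return KmerCounts(k, np.empty(0, np.uint64), np.empty(0, np.int64))
    allcodes = np.concatenate(chunks)
    allcounts = np.concatenate(wchunks)
    codes, inverse = np.unique(allcodes, return_inverse=True)
    counts = np.zeros(codes.size, dtype=np.int64)
    np.add.at(counts, inverse, allcounts)
    keep = (counts > min_occ) & (counts < max_occ)
    return KmerCounts(k, codes[keep], counts[keep])


@dataclass(frozen=True)
class KmerCountPair:
    """Merged male/female canonical k-mer table (union of both pools)."""

    k: int
    codes: np.ndarray
    male_counts: np.ndarray
    female_counts: np.ndarray

    def __len__(self) -> int:
        return int(self.codes.size)


def merge_pools(male: KmerCounts, female: KmerCounts) -> KmerCountPair:
    if male.k != female.k:
        raise ValueError(f"k mismatch: male k={male.k}, female k={female.k}")
    codes = np.union1d(male.codes, female.codes)
    m = np.zeros(codes.size, dtype=np.int64)
    f = np.zeros(codes.size, dtype=np.int64)
    m[np.searchsorted(codes, male.codes)] = male.counts
    f[np.searchsorted(codes, female.codes)] = female.counts
    return KmerCountPair(male.k, codes, m, f)


def merge_and_filter(
    male: KmerCounts,
    female: KmerCounts,
    high: int = DEFAULT_HIGH,
    low: int = DEFAULT_LOW,
) -> tuple[list[str], list[str]]:
    """Extract sex-biased k-mers from two pool tables.

    A k-mer is male-specific iff its male count is strictly greater than
    ``high`` and its female count strictly less than ``low``; symmetric
    for female-specific. Both comparisons are strict.
    """
    pair = merge_pools(male, female)
    male_mask = (pair.male_counts > high) & (pair.female_counts < low)
    female_mask = (pair.female_counts > high) & (pair.male_counts < low)
    k = pair.k
    male_specific = [code_to_kmer(int(c), k) for c in pair.codes[male_mask]]
    female_specific = [code_to_kmer(int(c), k) for c in pair.codes[female_mask]]
    return male_specific, female_specific


@dataclass(frozen=True)
class HeterogametyCall:
    system: str  # "XY", "ZW" or "UNDETERMINED"
    ratio: float  # dominant/minor specific-k-mer ratio (may be inf)
    ratio_display: str
    n_male_specific: int
    n_female_specific: int


def infer_heterogamety(
    n_male_specific: int,
    n_female_specific: int,
    ratio_threshold: float = 10.0,
    min_count: int = 1000,
) -> HeterogametyCall:
    """Call the heterogametic sex from sex-specific k-mer counts.

    ZW iff female-specific k-mers outnumber male-specific ones by at least
    ``ratio_threshold`` and reach ``min_count``; XY symmetric; otherwise
    undetermined. The threshold and floor are reporting conventions, not
    estimated quantities; both appear in the report.
    """
    if n_male_specific < 0 or n_female_specific < 0:
        raise ValueError("k-mer counts must be non-negative")
    nm, nf = n_male_specific, n_female_specific
    hi, lo = max(nm, nf), min(nm, nf)
    ratio = float("inf") if lo == 0 and hi > 0 else (hi / lo if lo else 0.0)
    display = f">{ratio_threshold:g}" if ratio == float("inf") else f"{ratio:.1f}"
    system = "UNDETERMINED"
    if nf >= min_count and nm * ratio_threshold <= nf:
        system = "ZW"
    elif nm >= min_count and nf * ratio_threshold <= nm:
        system = "XY"
    return HeterogametyCall(system, ratio, display, nm, nf)


def write_kmer_table(table: KmerCounts, path: str | Path) -> None:
    with open(path, "w") as fh:
        for kmer, count in table.items():
            fh.write(f"{kmer}\t{count}\n")


def read_kmer_table(path: str | Path) -> KmerCounts:
    kmers: list[int] = []
    counts: list[int] = []
    k = None
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'kmer<TAB>count'")
        if k is None:
            k = len(fields[0])
        elif len(fields[0]) != k:
            raise ValueError(f"{path}:{lineno}: inconsistent k-mer length")
        kmers.append(kmer_to_code(canonicalize(fields[0])))
        counts.append(int(fields[1]))
    if k is None:
        return KmerCounts(DEFAULT_K, np.empty(0, np.uint64), np.empty(0, np.int64))
    order = np.argsort(np.asarray(kmers, dtype=np.uint64))
    return KmerCounts(
        k,
        np.asarray(kmers, dtype=np.uint64)[order],
        np.asarray(counts, dtype=np.int64)[order],
    )


def write_merged_table(pair: KmerCountPair, path: str | Path) -> None:
    with open(path, "w") as fh:
        for code, m, f in zip(pair.codes, pair.male_counts, pair.female_counts):
            fh.write(f"{code_to_kmer(int(code), pair.k)}\t{m}\t{f}\n")
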