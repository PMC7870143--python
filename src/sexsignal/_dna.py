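"""Low-level DNA utilities shared by the simulator and the k-mer module.

Sequences are handled either as Python strings (ACGT) or as numpy uint8
code arrays with A=0, C=1, G=2, T=3; non-ACGT symbols map to code 4.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Sequence string -> uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def random_bases(rng: np.random.Generator, n: int) -> str:
    return decode(rng.integers(0, 4, size=n, dtype=np.uint8))
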