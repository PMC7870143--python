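"""Population map: phenotypic sex registry for a sample of individuals.

A popmap is the standard two-column TSV used throughout RAD-seq sex-linkage
studies: one line per individual, ``individual<TAB>M|F``.
"""

from __future__ import annotations

from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

MALE = "M"
FEMALE = "F"


@dataclass(frozen=True)
class PopMap(Mapping):
    """Immutable mapping from individual ID to phenotypic sex ('M' or 'F')."""

    sexes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ind, sex in self.sexes.items():
            if sex not in (MALE, FEMALE):
                raise ValueError(f"invalid sex {sex!r} for individual {ind!r}")

    def __getitem__(self, ind: str) -> str:
        return self.sexes[ind]

    def __iter__(self) -> Iterator[str]:
        return iter(self.sexes)

    def __len__(self) -> int:
        return len(self.sexes)

    @property
    def males(self) -> list[str]:
        return [i for i, s in self.sexes.items() if s == MALE]

    @property
    def females(self) -> list[str]:
        return [i for i, s in self.sexes.items() if s == FEMALE]

    def swapped(self) -> "PopMap":
        """Popmap with every sex label flipped (polarity-mirror helper)."""
        flip = {MALE: FEMALE, FEMALE: MALE}
        return PopMap({i: flip[s] for i, s in self.sexes.items()})


def read_popmap(path: str | Path) -> PopMap:
    sexes: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'individual<TAB>M|F'")
        ind, sex = fields
        if ind in sexes:
            raise ValueError(f"{path}:{lineno}: duplicate individual {ind!r}")
        sexes[ind] = sex
    return PopMap(sexes)


def write_popmap(popmap: PopMap, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{ind}\t{sex}\n" for ind, sex in popmap.sexes.items())
    )
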