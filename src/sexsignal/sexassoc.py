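"""Presence/absence sex-linkage association testing.

Given carrier status of a candidate sex-determining sequence (e.g. a
male-specific *amh* duplicate) for phenotypically sexed individuals, this
module tests whether carrier status is associated with phenotypic sex using
the Pearson chi-square test with Yates continuity correction on the 2x2
table (males/females x carrier/non-carrier), one degree of freedom.

The Yates-corrected statistic for a table ``[[a, b], [c, d]]`` with total
``n = a + b + c + d`` is

    chi2 = n * (max(|ad - bc| - n/2, 0))^2 / ((a+b)(c+d)(a+c)(b+d))

and the p-value is the upper tail of the chi-square distribution with one
degree of freedom.  Tables with a zero margin (e.g. the marker absent from
every individual) carry no association information and are reported as
degenerate with p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from scipy.stats import chi2 as _chi2_dist

from .popmap import MALE, PopMap

#: p-values below this are printed as "<2.2E-16" in human-readable output,
#: following the conventional R-style floor; raw floats are kept in machine
#: output.
P_FLOOR = 2.2e-16


@dataclass(frozen=True)
class PresenceTable:
    """2x2 carrier-by-sex contingency table.

    a: carrier males, b: non-carrier males,
    c: carrier females, d: non-carrier females.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.n < 1:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_margin(self) -> bool:
        return 0 in (
            self.a + self.b,
            self.c + self.d,
            self.a + self.c,
            self.b + self.d,
        )


@dataclass(frozen=True)
class AssociationResult:
    chi2: float
    p: float
    df: int = 1
    continuity_corrected: bool = True
    degenerate: bool = False

    def format_p(self) -> str:
        """p formatted for reports, with the conventional floor."""
        return "<2.2E-16" if self.p < P_FLOOR else format(self.p, ".3g")


def yates_chi2(table: PresenceTable) -> AssociationResult:
    """Yates-corrected chi-square test of a 2x2 presence table.

    Zero-margin tables are degenerate: chi2 = 0, p = 1. The continuity
    correction is clamped so the statistic is never negative.
    """
    if table.has_zero_margin:
        return AssociationResult(chi2=0.0, p=1.0, degenerate=True)
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    num = max(abs(a * d - b * c) - n / 2.0, 0.0)
    den = float((a + b) * (c + d) * (a + c) * (b + d))
    stat = n * num * num / den
    return AssociationResult(chi2=stat, p=float(_chi2_dist.sf(stat, 1)))


def test_sex_linkage(
    popmap: PopMap, presence: dict[str, bool]
) -> tuple[AssociationResult, PresenceTable]:
    """Cross-tabulate sex x carrier status and test for association.

    ``presence`` maps individual ID to carrier flag; every individual must
    appear in the popmap.
    """
    if not presence:
        raise ValueError("no carrier-status records supplied")
    unknown = sorted(set(presence) - set(popmap))
    if unknown:
        raise KeyError(f"individuals not in popmap: {', '.join(unknown)}")
    a = b = c = d = 0
    for ind, carrier in presence.items():
        if popmap[ind] == MALE:
            a, b = (a + 1, b) if carrier else (a, b + 1)
        else:
            c, d = (c + 1, d) if carrier else (c, d + 1)
    table = PresenceTable(a, b, c, d)
    return yates_chi2(table), table


def read_presence(path: str | Path) -> dict[str, bool]:
    """Read a carrier-status TSV: ``individual<TAB>0|1``."""
    presence: dict[str, bool] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2 or fields[1] not in ("0", "1"):
            raise ValueError(f"{path}:{lineno}: expected 'individual<TAB>0|1'")
        presence[fields[0]] = fields[1] == "1"
    return presence
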