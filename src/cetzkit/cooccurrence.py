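"""Species-level co-occurrence of CetZ subfamilies and reported phenotypes.

Venn-style tallies of CetZ1/CetZ2 presence against reported motility and
rod shape across species. Counts are raw enumerations: a species with no
phenotype report contributes only to the marginals it satisfies, because
absence of a report is not evidence of absence. No significance testing is
attached — the tallies describe, they do not test.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

import pandas as pd

from .io_formats import SpeciesPhenotypeRecord

_BOOL_FIELDS = ("has_cetz1", "has_cetz2", "motility_reported", "rods_reported")


@dataclass(frozen=True)
class VennTally:
    """Cross-species counts of subfamily presence and phenotype co-occurrence."""

    n_species: int = 0
    n_both: int = 0
    n_cetz1_only: int = 0
    n_cetz2_only: int = 0
    n_neither: int = 0
    n_motile: int = 0
    n_motile_and_both: int = 0
    n_motile_and_cetz1_only: int = 0
    n_rod: int = 0
    n_rod_and_both: int = 0
    n_rod_and_cetz1_only: int = 0

    def __post_init__(self) -> None:
        if self.n_both + self.n_cetz1_only + self.n_cetz2_only + self.n_neither != self.n_species:
            raise ValueError("presence categories must partition the species")
        pairs = [
            (self.n_motile_and_both, min(self.n_motile, self.n_both)),
            (self.n_motile_and_cetz1_only, min(self.n_motile, self.n_cetz1_only)),
            (self.n_rod_and_both, min(self.n_rod, self.n_both)),
            (self.n_rod_and_cetz1_only, min(self.n_rod, self.n_cetz1_only)),
        ]
        if any(cond > marginal for cond, marginal in pairs):
            raise ValueError("a conditional count exceeds its marginal")
        if any(getattr(self, f.name) < 0 for f in fields(self)):
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{f.name: getattr(self, f.name) for f in fields(self)}]
        )


def tally_cooccurrence(records: Sequence[SpeciesPhenotypeRecord]) -> VennTally:
    """Direct enumeration of the Venn counts over a species table."""
    both = [r for r in records if r.has_cetz1 and r.has_cetz2]
    c1_only = [r for r in records if r.has_cetz1 and not r.has_cetz2]
    c2_only = [r for r in records if r.has_cetz2 and not r.has_cetz1]
    neither = [r for r in records if not r.has_cetz1 and not r.has_cetz2]
    return VennTally(
        n_species=len(records),
        n_both=len(both),
        n_cetz1_only=len(c1_only),
        n_cetz2_only=len(c2_only),
        n_neither=len(neither),
        n_motile=sum(r.motility_reported for r in records),
        n_motile_and_both=sum(r.motility_reported for r in both),
        n_motile_and_cetz1_only=sum(r.motility_reported for r in c1_only),
        n_rod=sum(r.rods_reported for r in records),
        n_rod_and_both=sum(r.rods_reported for r in both),
        n_rod_and_cetz1_only=sum(r.rods_reported for r in c1_only),
    )


def crosstab(
    records: Sequence[SpeciesPhenotypeRecord], row_flag: str, col_flag: str
) -> pd.DataFrame:
    """2x2 contingency table of two boolean fields; cells sum to n_species."""
    for name in (row_flag, col_flag):
        if name not in _BOOL_FIELDS:
            raise KeyError(
                f"unknown boolean field {name!r}; one of {_BOOL_FIELDS}"
            )
    table = pd.DataFrame(0, index=[True, False], columns=[True, False])
    for r in records:
        table.loc[getattr(r, row_flag), getattr(r, col_flag)] += 1
    table.index.name = row_flag
    table.columns.name = col_flag
    return table
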