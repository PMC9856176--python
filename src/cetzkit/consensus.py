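"""Per-group consensus profiles and subfamily-discriminating residue calls.

The statistic: for each alignment column, each group's *consensus score* is
the percentage of its non-gap characters carrying the group's modal residue.
A column is a *unique residue* for a pair of groups when the two consensus
residues differ and the *unique residue score* — the arithmetic mean of the
two consensus scores — exceeds a threshold (90% is the usual subfamily-level
cut-off; 80% at the family level). Each call is further labelled by whether
the two consensus residues fall in the same side-chain chemistry class.

Also provided: scoring a query sequence against a unique-residue set (how
many of the discriminating positions it shares with each group's consensus)
and ungapped span lengths per sequence, used to profile loop regions such as
the tubulin M-loop (long, 14–26 residues, in CetZ1-like proteins; short,
3–6, in CetZ2-like ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import STANDARD_AA, GroupedAlignment

#: residues eligible to be a consensus residue, in tie-break (alphabetical) order
_CANDIDATES = np.frombuffer(STANDARD_AA.encode(), dtype=np.uint8)

DEFAULT_CHEMISTRY_CLASSES: dict[str, tuple[str, ...]] = {
    "nonpolar": ("G", "A", "V", "L", "I", "M", "P"),
    "aromatic": ("F", "W", "Y"),
    "polar-uncharged": ("S", "T", "C", "N", "Q"),
    "positive": ("K", "R", "H"),
    "negative": ("D", "E"),
}


@dataclass(frozen=True)
class ChemistryClasses:
    """Partition of the 20 standard amino acids into side-chain chemistry classes."""

    classes: Mapping[str, tuple[str, ...]]
    _residue_to_class: dict[str, str] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        mapping: dict[str, str] = {}
        for label, residues in self.classes.items():
            for r in residues:
                if r in mapping:
                    raise ValueError(f"residue {r!r} assigned to two classes")
                mapping[r] = label
        missing = sorted(set(STANDARD_AA) - set(mapping))
        if missing:
            raise ValueError(f"residues not assigned to any class: {missing}")
        object.__setattr__(self, "_residue_to_class", mapping)

    @classmethod
    def default(cls) -> "ChemistryClasses":
        return cls(DEFAULT_CHEMISTRY_CLASSES)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ChemistryClasses":
        """Read a 2-column TSV (residue, class_label)."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if list(df.columns[:2]) != ["residue", "class_label"]:
            raise ValueError(f"{path}: expected columns residue, class_label")
        grouped: dict[str, list[str]] = {}
        for row in df.itertuples(index=False):
            grouped.setdefault(row.class_label, []).append(row.residue)
        return cls({k: tuple(v) for k, v in grouped.items()})

    def class_of(self, residue: str) -> str:
        try:
            return self._residue_to_class[residue]
        except KeyError:
            raise KeyError(f"residue {residue!r} has no chemistry class") from None

    def relation(self, residue_a: str, residue_b: str) -> str:
        """'similar' if both residues share a class, else 'different'."""
        return "similar" if self.class_of(residue_a) == self.class_of(residue_b) else "different"


@dataclass(frozen=True)
class ColumnConsensus:
    """Consensus call for one alignment column within one group."""

    residue: str | None
    score: float  # percent of non-gap characters matching residue
    gap_fraction: float
    depth: int  # non-gap count
    tie: bool = False  # modal residue tied; broken alphabetically


@dataclass(frozen=True)
class ConsensusProfile:
    group_label: str
    columns: tuple[ColumnConsensus, ...]

    def __len__(self) -> int:
        return len(self.columns)


@dataclass(frozen=True)
class UniqueResidueCall:
    """A subfamily-discriminating column (0-based internally, 1-based in reports)."""

    column: int
    residue_a: str
    residue_b: str
    score_a: float
    score_b: float
    unique_score: float
    chemistry: str  # 'similar' or 'different'

    def __post_init__(self) -> None:
        if self.residue_a == self.residue_b:
            raise ValueError("unique residue call requires differing consensus residues")

    @property
    def column_1based(self) -> int:
        return self.column + 1


def _char_matrix(alignment: GroupedAlignment, group: str) -> np.ndarray:
    members = alignment.group_members(group)
    buf = "".join(r.gapped_sequence for r in members).encode()
    return np.frombuffer(buf, dtype=np.uint8).reshape(len(members), alignment.length)


def build_consensus(alignment: GroupedAlignment, group: str) -> ConsensusProfile:
    """Per-column modal residue and consensus score for one group.

    Gaps are excluded from both numerator and denominator of the score.
    Ambiguity codes (X/B/Z) count toward depth but can never be the consensus
    residue. Modal ties break alphabetically and are flagged.
    """
    mat = _char_matrix(alignment, group)
    n_members, n_cols = mat.shape
    counts = np.zeros((n_cols, 128), dtype=np.int64)
    cols = np.broadcast_to(np.arange(n_cols), mat.shape)
    np.add.at(counts, (cols.ravel(), mat.ravel()), 1)

    gap_counts = counts[:, ord("-")]
    depth = n_members - gap_counts
    cand = counts[:, _CANDIDATES]  # (n_cols, 20), alphabetical order
    best_idx = cand.argmax(axis=1)  # argmax keeps first max -> alphabetical tie-break
    best_count = cand[np.arange(n_cols), best_idx]
    tie = (cand == best_count[:, None]).sum(axis=1) > 1

    columns = []
    for c in range(n_cols):
        if depth[c] == 0 or best_count[c] == 0:
            columns.append(
                ColumnConsensus(None, 0.0, gap_counts[c] / n_members, int(depth[c]))
            )
        else:
            columns.append(
                ColumnConsensus(
                    residue=chr(_CANDIDATES[best_idx[c]]),
                    score=100.0 * best_count[c] / depth[c],
                    gap_fraction=gap_counts[c] / n_members,
                    depth=int(depth[c]),
                    tie=bool(tie[c] and best_count[c] > 0),
                )
            )
    return ConsensusProfile(group, tuple(columns))


def unique_residue_scores(
    profile_a: ConsensusProfile, profile_b: ConsensusProfile
) -> pd.DataFrame:
    """Per-column table pairing two groups' consensus calls.

    Columns: column_1based, residue_a, score_a, gap_fraction_a, tie_a, and
    the same for b, plus unique_score = (score_a + score_b) / 2. The
    unique_score vector is symmetric in argument order.
    """
    if len(profile_a) != len(profile_b):
        raise ValueError(
            f"column-count mismatch: {profile_a.group_label!r} has {len(profile_a)}, "
            f"{profile_b.group_label!r} has {len(profile_b)}"
        )
    rows = []
    for i, (a, b) in enumerate(zip(profile_a.columns, profile_b.columns)):
        rows.append(
            {
                "column_1based": i + 1,
                "residue_a": a.residue,
                "score_a": a.score,
                "gap_fraction_a": a.gap_fraction,
                "tie_a": a.tie,
                "residue_b": b.residue,
                "score_b": b.score,
                "gap_fraction_b": b.gap_fraction,
                "tie_b": b.tie,
                "unique_score": (a.score + b.score) / 2.0,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["group_a"] = profile_a.group_label
    df.attrs["group_b"] = profile_b.group_label
    return df


def call_unique_residues(
    score_table: pd.DataFrame,
    threshold_pct: float,
    chemistry: ChemistryClasses | None = None,
    strict: bool = True,
    max_gap_fraction: float = 0.5,
) -> list[UniqueResidueCall]:
    """Columns whose consensus residues differ with unique_score above threshold.

    *strict* keeps the "greater than" reading of the cut-off (set False for >=).
    Columns where either group is majority-gap (gap fraction above
    *max_gap_fraction*) are excluded: they have no meaningful consensus.
    Output is sorted by column.
    """
    if not 0 < threshold_pct <= 100:
        raise ValueError("threshold_pct must be in (0, 100]")
    chemistry = chemistry or ChemistryClasses.default()
    calls = []
    for row in score_table.itertuples(index=False):
        if row.residue_a is None or row.residue_b is None:
            continue
        if row.residue_a == row.residue_b:
            continue
        if row.gap_fraction_a > max_gap_fraction or row.gap_fraction_b > max_gap_fraction:
            continue
        passed = row.unique_score > threshold_pct if strict else row.unique_score >= threshold_pct
        if not passed:
            continue
        calls.append(
            UniqueResidueCall(
                column=row.column_1based - 1,
                residue_a=row.residue_a,
                residue_b=row.residue_b,
                score_a=row.score_a,
                score_b=row.score_b,
                unique_score=row.unique_score,
                chemistry=chemistry.relation(row.residue_a, row.residue_b),
            )
        )
    return sorted(calls, key=lambda c: c.column)


def calls_to_frame(calls: Sequence[UniqueResidueCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "column_1based": c.column_1based,
                "residue_a": c.residue_a,
                "score_a": c.score_a,
                "residue_b": c.residue_b,
                "score_b": c.score_b,
                "unique_score": c.unique_score,
                "chemistry": c.chemistry,
            }
            for c in calls
        ],
        columns=[
            "column_1based", "residue_a", "score_a", "residue_b", "score_b",
            "unique_score", "chemistry",
        ],
    )


def shared_unique_residues(
    alignment: GroupedAlignment,
    query_id: str,
    calls: Sequence[UniqueResidueCall],
    side: str,
) -> tuple[int, int]:
    """How many discriminating positions a query shares with one group's consensus.

    Returns (n_shared, n_total); a gap in the query never matches. Used to
    place atypical sequences (e.g. divergent homologues annotated to a
    subfamily they may not belong to) relative to two subfamilies.
    """
    if side not in {"a", "b"}:
        raise ValueError("side must be 'a' or 'b'")
    if not calls:
        raise ValueError("calls must be non-empty")
    query = alignment.record(query_id).gapped_sequence
    n_shared = 0
    for call in calls:
        target = call.residue_a if side == "a" else call.residue_b
        if query[call.column] == target:
            n_shared += 1
    return n_shared, len(calls)


def region_lengths(
    alignment: GroupedAlignment, column_span: tuple[int, int]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ungapped length of a column span, per sequence, with per-group summaries.

    *column_span* is (first_col, last_col), 1-based inclusive. Returns
    (per-sequence table, per-group min/median/max summary).
    """
    first, last = column_span
    if not 1 <= first <= last <= alignment.length:
        raise ValueError(
            f"span {column_span} out of range for alignment of length {alignment.length}"
        )
    rows = [
        {
            "sequence_id": r.sequence_id,
            "group_label": r.group_label,
            "ungapped_length": sum(
                ch != "-" for ch in r.gapped_sequence[first - 1 : last]
            ),
        }
        for r in alignment.records
    ]
    per_seq = pd.DataFrame(rows)
    summary = (
        per_seq.groupby("group_label")["ungapped_length"]
        .agg(["min", "median", "max"])
        .reset_index()
    )
    return per_seq, summary
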