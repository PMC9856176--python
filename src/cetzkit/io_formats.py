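"""Readers and writers for the external formats the pipeline touches.

Every downstream module consumes only the domain types defined here:
grouped multiple sequence alignments (aligned FASTA + a sequence→group
table), genome annotations (GFF3 or a feature-table TSV dialect, with
contig lengths and circularity declared explicitly), protein→arCOG
assignment tables as produced by an external annotator, and species
presence/phenotype tables.

Coordinates are 1-based inclusive everywhere (the GFF3 convention); any
half-open arithmetic stays internal to the functions that need it and is
never serialized.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.iterators import DataIterator

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: characters legal in a gapped alignment row (ambiguity codes kept literal)
ALIGNMENT_ALPHABET = frozenset(STANDARD_AA) | {"X", "B", "Z", "-"}

_TRUE_STRINGS = {"1", "true", "yes"}
_FALSE_STRINGS = {"0", "false", "no"}

ARCOG_COLUMNS = ["locus_id", "arcog_id", "cog_category", "annotation"]
SPECIES_COLUMNS = [
    "species",
    "taxon_order",
    "has_cetz1",
    "has_cetz2",
    "n_other_cetz",
    "motility_reported",
    "rods_reported",
]
CONTIG_COLUMNS = ["contig_id", "length_bp", "is_circular"]
FEATURE_TABLE_COLUMNS = ["contig_id", "start_bp", "end_bp", "strand", "locus_id", "product"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignedRecord:
    """One gapped sequence row of a grouped alignment."""

    sequence_id: str
    group_label: str
    gapped_sequence: str


@dataclass(frozen=True)
class GroupedAlignment:
    """Equal-length gapped amino-acid sequences, each tagged with a group label.

    The joint alignment makes column correspondence between groups explicit:
    per-group consensus profiles built from it are directly comparable
    column by column.
    """

    records: tuple[AlignedRecord, ...]
    length: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no records")
        lengths = {len(r.gapped_sequence) for r in self.records}
        if len(lengths) != 1:
            expected = len(self.records[0].gapped_sequence)
            bad = next(r for r in self.records if len(r.gapped_sequence) != expected)
            raise ValueError(
                f"ragged alignment: record {bad.sequence_id!r} has length "
                f"{len(bad.gapped_sequence)}, expected {expected}"
            )
        ids = [r.sequence_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")
        for r in self.records:
            extra = set(r.gapped_sequence) - ALIGNMENT_ALPHABET
            if extra:
                raise ValueError(
                    f"record {r.sequence_id!r} contains illegal characters {sorted(extra)}"
                )
        object.__setattr__(self, "length", lengths.pop())

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.group_label, None)
        return tuple(seen)

    def group_members(self, group_label: str) -> tuple[AlignedRecord, ...]:
        members = tuple(r for r in self.records if r.group_label == group_label)
        if not members:
            raise KeyError(
                f"unknown group {group_label!r}; known groups: {list(self.groups)}"
            )
        return members

    def record(self, sequence_id: str) -> AlignedRecord:
        for r in self.records:
            if r.sequence_id == sequence_id:
                return r
        raise KeyError(f"sequence id {sequence_id!r} not in alignment")


@dataclass(frozen=True)
class GeneFeature:
    """A protein-coding gene on a contig, 1-based inclusive coordinates."""

    contig_id: str
    start_bp: int
    end_bp: int
    strand: str
    locus_id: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start_bp < 1:
            raise ValueError(f"feature {self.locus_id!r}: start_bp {self.start_bp} < 1")
        if self.end_bp < self.start_bp:
            raise ValueError(
                f"feature {self.locus_id!r}: end_bp {self.end_bp} < start_bp {self.start_bp}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"feature {self.locus_id!r}: strand must be '+' or '-'")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass(frozen=True)
class Contig:
    contig_id: str
    length_bp: int
    is_circular: bool = False

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"contig {self.contig_id!r}: non-positive length")


@dataclass(frozen=True)
class GenomeAnnotation:
    """A genome's contigs and gene features, validated against contig bounds."""

    contigs: tuple[Contig, ...]
    features: tuple[GeneFeature, ...]

    def __post_init__(self) -> None:
        ids = [c.contig_id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate contig ids")
        by_id = {c.contig_id: c for c in self.contigs}
        loci = [f.locus_id for f in self.features]
        if len(set(loci)) != len(loci):
            dupes = sorted({x for x in loci if loci.count(x) > 1})
            raise ValueError(f"duplicate locus ids: {dupes}")
        for f in self.features:
            contig = by_id.get(f.contig_id)
            if contig is None:
                raise ValueError(
                    f"feature {f.locus_id!r} on unknown contig {f.contig_id!r}"
                )
            if f.end_bp > contig.length_bp:
                raise ValueError(
                    f"feature {f.locus_id!r} ends at {f.end_bp} beyond contig "
                    f"{f.contig_id!r} length {contig.length_bp}"
                )

    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.contig_id == contig_id:
                return c
        raise KeyError(f"unknown contig {contig_id!r}")

    def feature(self, locus_id: str) -> GeneFeature:
        for f in self.features:
            if f.locus_id == locus_id:
                return f
        raise KeyError(f"unknown locus {locus_id!r}")


@dataclass(frozen=True)
class ArcogAssignment:
    """One locus's arCOG call; an empty arcog_id marks an unassigned locus."""

    locus_id: str
    arcog_id: str = ""
    cog_category: str = ""
    annotation: str = ""

    @property
    def is_assigned(self) -> bool:
        return bool(self.arcog_id)


@dataclass(frozen=True)
class SpeciesPhenotypeRecord:
    """CetZ subfamily presence and reported phenotypes for one species.

    Absence of a motility/rod report is not evidence of absence: species may
    simply lack published observations, so False means "not reported", never
    "reported negative".
    """

    species: str
    taxon_order: str
    has_cetz1: bool
    has_cetz2: bool
    n_other_cetz: int
    motility_reported: bool
    rods_reported: bool

    def __post_init__(self) -> None:
        if self.n_other_cetz < 0:
            raise ValueError(f"{self.species!r}: n_other_cetz must be >= 0")


# ---------------------------------------------------------------------------
# Grouped alignment I/O
# ---------------------------------------------------------------------------


def read_grouped_alignment(alignment_path: str | Path, groups_path: str | Path) -> GroupedAlignment:
    """Read an aligned FASTA plus a 2-column TSV (sequence_id, group_label).

    Residues are upper-cased and '.' gap characters normalized to '-'.
    Raises if the alignment is ragged or any FASTA id is missing from the
    groups table.
    """
    groups = _read_groups_table(groups_path)
    records = []
    for rec in SeqIO.parse(str(alignment_path), "fasta"):
        seq = str(rec.seq).upper().replace(".", "-")
        if rec.id not in groups:
            continue  # collect all first, then report missing ids together
        records.append(AlignedRecord(rec.id, groups[rec.id], seq))
    all_ids = [rec.id for rec in SeqIO.parse(str(alignment_path), "fasta")]
    missing = [i for i in all_ids if i not in groups]
    if missing:
        raise ValueError(f"sequence ids missing from groups table: {missing}")
    if not all_ids:
        raise ValueError(f"no FASTA records in {alignment_path}")
    return GroupedAlignment(tuple(records))


def _read_groups_table(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["sequence_id", "group_label"]:
        # headerless dialect: two bare columns
        df = pd.read_csv(
            path, sep="\t", dtype=str, keep_default_na=False,
            header=None, names=["sequence_id", "group_label"],
        )
    dupes = df["sequence_id"][df["sequence_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate sequence ids in groups table: {sorted(set(dupes))}")
    return dict(zip(df["sequence_id"], df["group_label"]))


def write_grouped_alignment(
    alignment: GroupedAlignment, alignment_path: str | Path, groups_path: str | Path
) -> None:
    seqs = [
        SeqRecord(Seq(r.gapped_sequence), id=r.sequence_id, description="")
        for r in alignment.records
    ]
    SeqIO.write(seqs, str(alignment_path), "fasta")
    df = pd.DataFrame(
        {
            "sequence_id": [r.sequence_id for r in alignment.records],
            "group_label": [r.group_label for r in alignment.records],
        }
    )
    df.to_csv(groups_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genome annotation I/O
# ---------------------------------------------------------------------------


def read_annotation(
    path: str | Path,
    contigs_path: str | Path | None = None,
    circular_contigs: Iterable[str] = (),
) -> GenomeAnnotation:
    """Read gene features from GFF3 or the feature-table TSV dialect.

    Contig lengths come from GFF3 ``##sequence-region`` pragmas or a sidecar
    contigs table (required for the TSV dialect); circularity is declared via
    *circular_contigs* or the sidecar's ``is_circular`` column, never guessed
    from the annotation.
    """
    path = Path(path)
    circular = set(circular_contigs)
    sidecar = read_contig_table(contigs_path) if contigs_path is not None else []
    if path.suffix.lower() in {".gff", ".gff3"}:
        contigs, features = _read_gff3(path)
    else:
        contigs, features = [], _read_feature_table(path)
    by_id: dict[str, Contig] = {c.contig_id: c for c in contigs}
    for c in sidecar:  # sidecar wins over pragmas
        by_id[c.contig_id] = c
    if not by_id:
        raise ValueError(
            f"{path}: no contig lengths found (no ##sequence-region pragmas and "
            "no contigs table supplied)"
        )
    merged = tuple(
        replace(c, is_circular=c.is_circular or c.contig_id in circular)
        for c in by_id.values()
    )
    return GenomeAnnotation(merged, tuple(features))


def _read_gff3(path: Path) -> tuple[list[Contig], list[GeneFeature]]:
    contigs: list[Contig] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, seqid, start, end = line.split()[:4]
                contigs.append(Contig(seqid, int(end) - int(start) + 1))
            elif line.startswith("##FASTA"):
                break
    features = []
    for feat in DataIterator(str(path)):
        if feat.featuretype not in {"gene", "CDS"}:
            continue
        locus = (
            feat.attributes.get("locus_tag")
            or feat.attributes.get("ID")
            or feat.attributes.get("Name")
        )
        if locus is None:
            raise ValueError(f"{path}: feature at {feat.seqid}:{feat.start} has no id")
        product = (feat.attributes.get("product") or [""])[0]
        features.append(
            GeneFeature(feat.seqid, feat.start, feat.end, feat.strand, locus[0], product)
        )
    # a gene and its CDS share a locus id; keep the first (gene) row
    seen: dict[str, GeneFeature] = {}
    for f in features:
        seen.setdefault(f.locus_id, f)
    return contigs, list(seen.values())


def _read_feature_table(path: Path) -> list[GeneFeature]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: feature table missing columns {missing}")
    return [
        GeneFeature(
            row.contig_id, int(row.start_bp), int(row.end_bp), row.strand,
            row.locus_id, row.product,
        )
        for row in df.itertuples(index=False)
    ]


def write_annotation(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write GFF3 with ##sequence-region pragmas (circularity goes in a sidecar)."""
    lines = ["##gff-version 3"]
    for c in annotation.contigs:
        lines.append(f"##sequence-region {c.contig_id} 1 {c.length_bp}")
    for f in sorted(annotation.features, key=lambda x: (x.contig_id, x.start_bp, x.locus_id)):
        attrs = f"ID={f.locus_id};locus_tag={f.locus_id}"
        if f.product:
            attrs += f";product={f.product}"
        lines.append(
            "\t".join(
                [f.contig_id, "cetzkit", "gene", str(f.start_bp), str(f.end_bp),
                 ".", f.strand, ".", attrs]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_contig_table(path: str | Path) -> list[Contig]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CONTIG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: contigs table missing columns {missing}")
    return [
        Contig(row.contig_id, int(row.length_bp), _parse_bool(row.is_circular, path, i + 2))
        for i, row in enumerate(df.itertuples(index=False))
    ]


def write_contig_table(contigs: Sequence[Contig], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "contig_id": [c.contig_id for c in contigs],
            "length_bp": [c.length_bp for c in contigs],
            "is_circular": [int(c.is_circular) for c in contigs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# arCOG assignment tables
# ---------------------------------------------------------------------------


def read_arcog_table(path: str | Path) -> list[ArcogAssignment]:
    """Read a locus→arCOG TSV (as produced by an external annotator).

    One row per locus; an empty arcog_id field is retained and flagged
    unassigned. Duplicate loci are an error — multi-hit resolution belongs
    upstream.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ARCOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: arCOG table missing columns {missing}")
    dupes = df["locus_id"][df["locus_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate locus ids: {sorted(set(dupes))}")
    return [
        ArcogAssignment(row.locus_id, row.arcog_id, row.cog_category, row.annotation)
        for row in df.itertuples(index=False)
    ]


def write_arcog_table(assignments: Sequence[ArcogAssignment], path: str | Path) -> None:
    df = pd.DataFrame(
        [[a.locus_id, a.arcog_id, a.cog_category, a.annotation] for a in assignments],
        columns=ARCOG_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Species phenotype tables
# ---------------------------------------------------------------------------


def _parse_bool(value: str, path: str | Path, row_number: int) -> bool:
    v = str(value).strip().lower()
    if v in _TRUE_STRINGS:
        return True
    if v in _FALSE_STRINGS:
        return False
    raise ValueError(f"{path}: row {row_number}: unparseable boolean {value!r}")


def read_species_table(path: str | Path) -> list[SpeciesPhenotypeRecord]:
    """Read the species presence/phenotype TSV (booleans: 0/1, true/false, yes/no)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SPECIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: species table missing columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        rownum = i + 2  # 1-based, counting the header line
        records.append(
            SpeciesPhenotypeRecord(
                species=row.species,
                taxon_order=row.taxon_order,
                has_cetz1=_parse_bool(row.has_cetz1, path, rownum),
                has_cetz2=_parse_bool(row.has_cetz2, path, rownum),
                n_other_cetz=int(row.n_other_cetz),
                motility_reported=_parse_bool(row.motility_reported, path, rownum),
                rods_reported=_parse_bool(row.rods_reported, path, rownum),
            )
        )
    return records


def write_species_table(records: Sequence[SpeciesPhenotypeRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            [r.species, r.taxon_order, int(r.has_cetz1), int(r.has_cetz2),
             r.n_other_cetz, int(r.motility_reported), int(r.rods_reported)]
            for r in records
        ],
        columns=SPECIES_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
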