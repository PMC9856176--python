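"""Gene-neighbourhood extraction, arCOG conservation, and regulon classification.

A *neighbourhood region* is the fixed-flank genomic window around a focal
gene (default 20 kb either side of the gene boundaries, i.e. a ~40 kb
region), truncated at linear contig ends and wrapped across the origin of
circular contigs. Member genes are labelled with arCOG orthologous-group
ids, tallied across species as both raw *occurrences* (total gene count)
and *presence* (number of regions containing the arCOG at least once), and
conserved arCOGs are those present in at least a chosen number of regions
(default: a majority).

A region is classified *pili-associated* when it carries a type IV pilus
cassette: a run of regulon genes, anchored by distinct anchor arCOGs
(pilB, the assembly ATPase, and pilC, the membrane platform), interrupted
by at most a small number of non-regulon genes. Genome-wide placement of a
target arCOG relative to the focal region and to off-region regulon copies
supports synteny questions such as whether an arCOG travels with the
cassette or with the focal gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import ArcogAssignment, Contig, GeneFeature, GenomeAnnotation

DEFAULT_FLANK_BP = 20_000

#: arCOG of the pilB assembly ATPase (type IV pilus motor)
PILB_ARCOG = "arCOG01818"
#: the pilC platform protein's arCOG id is annotation-source specific; this
#: sentinel is the default anchor label and should be overridden to match
#: the id your annotator emits
PILC_ARCOG = "pilC"
#: predicted pilin (filament subunit) arCOGs recurrently found in
#: CetZ-adjacent type IV pilus regions
DEFAULT_PILIN_ARCOGS = (
    "arCOG05787",
    "arCOG05789",
    "arCOG03821",
    "arCOG03822",
    "arCOG05790",
    "arCOG05786",
    "arCOG05788",
)


@dataclass(frozen=True)
class RegulonDefinition:
    """What counts as a type IV pilus cassette.

    anchor_arcogs: arCOGs that define the regulon (pilB/pilC by default);
    accessory_arcogs: pilins and other cassette members that extend a match
    but never trigger one alone; min_anchors: distinct anchors required;
    max_gene_gap: tolerated non-regulon genes between consecutive cassette
    genes (unassigned genes count as interruptions).
    """

    anchor_arcogs: frozenset[str] = frozenset({PILB_ARCOG, PILC_ARCOG})
    accessory_arcogs: frozenset[str] = frozenset(DEFAULT_PILIN_ARCOGS)
    min_anchors: int = 2
    max_gene_gap: int = 3

    def __post_init__(self) -> None:
        if self.min_anchors > len(self.anchor_arcogs):
            raise ValueError("min_anchors exceeds the number of anchor arCOGs")
        if self.max_gene_gap < 0:
            raise ValueError("max_gene_gap must be >= 0")

    @property
    def member_arcogs(self) -> frozenset[str]:
        return self.anchor_arcogs | self.accessory_arcogs


@dataclass(frozen=True)
class RegionMember:
    """A gene inside a neighbourhood window, with its window-local coordinates.

    offset_start/offset_end are 0-based positions along the window (wrap
    already resolved), so member order and spacing are comparable across
    contig topologies.
    """

    feature: GeneFeature
    arcog_id: str | None = None  # None = not yet annotated / unassigned
    offset_start: int = 0
    offset_end: int = 0

    @property
    def is_assigned(self) -> bool:
        return bool(self.arcog_id)


@dataclass(frozen=True)
class NeighborhoodRegion:
    species: str
    focal_locus: str
    contig_id: str
    intervals: tuple[tuple[int, int], ...]  # 1-based inclusive; 2 pieces when wrapping
    members: tuple[RegionMember, ...]  # ordered along the window, focal included
    flank_bp: int = DEFAULT_FLANK_BP
    is_circular: bool = False

    @property
    def window_length_bp(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)

    @property
    def focal_member(self) -> RegionMember:
        for m in self.members:
            if m.feature.locus_id == self.focal_locus:
                return m
        raise ValueError(f"focal locus {self.focal_locus!r} not among members")

    def member_arcogs(self) -> list[str]:
        return [m.arcog_id for m in self.members if m.arcog_id]


@dataclass(frozen=True)
class OccurrenceTable:
    """Cross-region arCOG tallies: total occurrences and per-region presence."""

    n_regions: int
    occurrences: Mapping[str, int]
    presence: Mapping[str, int]
    annotations: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for arcog, pres in self.presence.items():
            if pres > self.occurrences.get(arcog, 0):
                raise ValueError(f"{arcog}: presence exceeds occurrences")
            if pres > self.n_regions:
                raise ValueError(f"{arcog}: presence exceeds number of regions")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "arcog_id": a,
                "occurrences": self.occurrences[a],
                "presence": self.presence[a],
                "annotation": self.annotations.get(a, ""),
            }
            for a in self.occurrences
        ]
        df = pd.DataFrame(rows, columns=["arcog_id", "occurrences", "presence", "annotation"])
        return df.sort_values(
            ["occurrences", "presence", "arcog_id"], ascending=[False, False, True]
        ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------


def _window_intervals(
    focal: GeneFeature, contig: Contig, flank_bp: int
) -> tuple[tuple[tuple[int, int], ...], int]:
    """Return the window's 1-based interval(s) and the window start (unclipped,
    possibly < 1 on circular contigs) used as the origin for offsets."""
    raw_start = focal.start_bp - flank_bp
    raw_end = focal.end_bp + flank_bp
    L = contig.length_bp
    if not contig.is_circular:
        return ((max(1, raw_start), min(L, raw_end)),), max(1, raw_start)
    if raw_end - raw_start + 1 >= L:
        return ((1, L),), 1
    start = (raw_start - 1) % L + 1
    end = (raw_end - 1) % L + 1
    if start <= end:
        return ((start, end),), raw_start
    return ((start, L), (1, end)), raw_start


def _circular_offset(pos: int, origin: int, L: int) -> int:
    """0-based offset of 1-based position *pos* from 1-based origin, mod L."""
    return (pos - origin) % L


def extract_neighborhood(
    annotation: GenomeAnnotation,
    focal_locus: str,
    flank_bp: int = DEFAULT_FLANK_BP,
    species: str = "",
) -> NeighborhoodRegion:
    """All genes overlapping the fixed-flank window around a focal gene.

    The window spans focal start − flank through focal end + flank, clipped
    at linear contig boundaries and wrapped across a circular origin. Genes
    partially overlapping the window are included whole; members are sorted
    by position along the window (wrap-aware), so the focal gene sits at
    offset flank_bp on an unclipped window.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    focal = annotation.feature(focal_locus)
    contig = annotation.contig(focal.contig_id)
    intervals, origin = _window_intervals(focal, contig, flank_bp)
    L = contig.length_bp

    members = []
    for f in annotation.features:
        if f.contig_id != contig.contig_id:
            continue
        if not any(f.start_bp <= e and f.end_bp >= s for s, e in intervals):
            continue
        if contig.is_circular:
            off_start = _circular_offset(f.start_bp, origin, L)
            off_end = off_start + f.length_bp - 1
        else:
            off_start = f.start_bp - origin
            off_end = f.end_bp - origin
        members.append(RegionMember(f, None, off_start, off_end))
    members.sort(key=lambda m: (m.offset_start, m.feature.locus_id))
    return NeighborhoodRegion(
        species=species,
        focal_locus=focal_locus,
        contig_id=contig.contig_id,
        intervals=intervals,
        members=tuple(members),
        flank_bp=flank_bp,
        is_circular=contig.is_circular,
    )


def annotate_region(
    region: NeighborhoodRegion, assignments: Sequence[ArcogAssignment]
) -> NeighborhoodRegion:
    """Attach arCOG labels to region members; absent loci become unassigned ('')."""
    table = {a.locus_id: a.arcog_id for a in assignments}
    members = tuple(
        replace(m, arcog_id=table.get(m.feature.locus_id, ""))
        for m in region.members
    )
    return replace(region, members=members)


# ---------------------------------------------------------------------------
# Tallies and conservation
# ---------------------------------------------------------------------------


def tally_arcogs(
    regions: Sequence[NeighborhoodRegion],
    annotations: Mapping[str, str] | None = None,
) -> OccurrenceTable:
    """Count arCOG occurrences and per-region presence across regions.

    Focal genes are included: a region that holds a second copy of the focal
    gene's arCOG contributes two occurrences but one presence. Unassigned
    members are excluded from the tallies.
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    occurrences: dict[str, int] = {}
    presence: dict[str, int] = {}
    for region in regions:
        arcogs = region.member_arcogs()
        for a in arcogs:
            occurrences[a] = occurrences.get(a, 0) + 1
        for a in set(arcogs):
            presence[a] = presence.get(a, 0) + 1
    return OccurrenceTable(
        n_regions=len(regions),
        occurrences=occurrences,
        presence=presence,
        annotations=dict(annotations or {}),
    )


def conserved_arcogs(table: OccurrenceTable, min_presence: int | None = None) -> set[str]:
    """arCOGs present in at least *min_presence* regions (default: majority)."""
    if min_presence is None:
        min_presence = math.ceil(table.n_regions / 2)
    if not 1 <= min_presence <= table.n_regions:
        raise ValueError(
            f"min_presence must be in [1, {table.n_regions}], got {min_presence}"
        )
    return {a for a, p in table.presence.items() if p >= min_presence}


# ---------------------------------------------------------------------------
# Pili-regulon classification
# ---------------------------------------------------------------------------


def _regulon_runs(
    region: NeighborhoodRegion, regulon: RegulonDefinition
) -> list[list[RegionMember]]:
    """Maximal runs of regulon-member genes separated by <= max_gene_gap others."""
    runs: list[list[RegionMember]] = []
    current: list[RegionMember] = []
    gap = 0
    for m in region.members:
        if m.arcog_id in regulon.member_arcogs:
            current.append(m)
            gap = 0
        elif current:
            gap += 1  # unassigned genes count as interruptions
            if gap > regulon.max_gene_gap:
                runs.append(current)
                current = []
                gap = 0
    if current:
        runs.append(current)
    return runs


def classify_pili_association(
    region: NeighborhoodRegion, regulon: RegulonDefinition | None = None
) -> tuple[bool, list[str]]:
    """Does the region carry an intact type IV pilus cassette?

    True iff some run of regulon genes (tolerating up to max_gene_gap
    intervening non-regulon genes) contains at least min_anchors distinct
    anchor arCOGs. matched_loci lists the genes of every qualifying run, in
    window order.
    """
    regulon = regulon or RegulonDefinition()
    matched: list[str] = []
    for run in _regulon_runs(region, regulon):
        anchors = {m.arcog_id for m in run if m.arcog_id in regulon.anchor_arcogs}
        if len(anchors) >= regulon.min_anchors:
            matched.extend(m.feature.locus_id for m in run)
    return bool(matched), matched


def _gene_distance_bp(a: GeneFeature, b: GeneFeature, contig: Contig) -> int:
    """Gap between two gene spans on a contig (0 if overlapping), circular-aware."""
    if a.start_bp > b.start_bp or (a.start_bp == b.start_bp and a.end_bp < b.end_bp):
        a, b = b, a
    if b.start_bp <= a.end_bp:
        return 0
    linear = b.start_bp - a.end_bp - 1
    if not contig.is_circular:
        return linear
    around = contig.length_bp - (b.end_bp - a.start_bp + 1)
    return min(linear, max(around, 0))


def genome_wide_arcog_placement(
    annotation: GenomeAnnotation,
    assignments: Sequence[ArcogAssignment],
    target_arcog: str,
    region: NeighborhoodRegion,
    regulon: RegulonDefinition | None = None,
    flank_bp: int | None = None,
) -> str:
    """Where does a target arCOG sit relative to a focal region?

    Returns the first matching category of: 'in_focal_region' (a target
    locus is a member of the region), 'elsewhere_with_regulon' (a target
    locus outside the region lies within flank_bp of >= min_anchors distinct
    regulon anchors that are themselves outside the region),
    'elsewhere_alone', or 'absent' (no locus of the target arCOG at all).
    """
    regulon = regulon or RegulonDefinition()
    flank_bp = flank_bp if flank_bp is not None else region.flank_bp
    by_locus = {a.locus_id: a.arcog_id for a in assignments}
    region_loci = {m.feature.locus_id for m in region.members}

    target_loci = [f for f in annotation.features if by_locus.get(f.locus_id) == target_arcog]
    if not target_loci:
        return "absent"
    if any(f.locus_id in region_loci for f in target_loci):
        return "in_focal_region"

    anchor_loci = [
        f
        for f in annotation.features
        if by_locus.get(f.locus_id) in regulon.anchor_arcogs
        and f.locus_id not in region_loci
    ]
    for target in target_loci:
        contig = annotation.contig(target.contig_id)
        near_anchors = {
            by_locus[f.locus_id]
            for f in anchor_loci
            if f.contig_id == target.contig_id
            and _gene_distance_bp(target, f, contig) <= flank_bp
        }
        if len(near_anchors) >= regulon.min_anchors:
            return "elsewhere_with_regulon"
    return "elsewhere_alone"


# ---------------------------------------------------------------------------
# Synteny maps
# ---------------------------------------------------------------------------


def synteny_table(
    regions: Sequence[NeighborhoodRegion], conserved: Iterable[str]
) -> pd.DataFrame:
    """Focal-gene-relative gene maps, comparable across species.

    Offsets are in bp from the focal gene start, signed along the focal gene's
    reading direction (the focal gene is always drawn left-to-right), so a
    region whose focal gene sits on the minus strand is mirror-reflected.
    arCOGs outside the conserved set are collapsed to 'other'; unassigned
    genes to 'unassigned'.
    """
    conserved = set(conserved)
    rows = []
    for region in regions:
        focal = region.focal_member
        flip = focal.feature.strand == "-"
        for m in region.members:
            if flip:
                offset = focal.offset_end - m.offset_end
                strand_rel = "+" if m.feature.strand == "-" else "-"
            else:
                offset = m.offset_start - focal.offset_start
                strand_rel = m.feature.strand
            if not m.arcog_id:
                label = "unassigned"
            elif m.arcog_id in conserved:
                label = m.arcog_id
            else:
                label = "other"
            rows.append(
                {
                    "species": region.species,
                    "focal_locus": region.focal_locus,
                    "locus_id": m.feature.locus_id,
                    "offset_bp": offset,
                    "length_bp": m.feature.length_bp,
                    "strand": strand_rel,
                    "label": label,
                    "is_focal": m.feature.locus_id == region.focal_locus,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "species", "focal_locus", "locus_id", "offset_bp", "length_bp",
            "strand", "label", "is_focal",
        ],
    )
    return df.sort_values(["species", "focal_locus", "offset_bp"]).reset_index(drop=True)


def render_synteny_map(table: pd.DataFrame, path: str) -> None:
    """Draw the synteny table as one row of gene arrows per region (SVG/PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    region_keys = list(dict.fromkeys(zip(table["species"], table["focal_locus"])))
    labels = sorted(set(table["label"]) - {"other", "unassigned"})
    cmap = plt.get_cmap("tab20")
    colors = {lab: cmap(i % 20) for i, lab in enumerate(labels)}
    colors["other"] = (1, 1, 1, 1)
    colors["unassigned"] = (0.85, 0.85, 0.85, 1)

    fig, ax = plt.subplots(figsize=(10, 0.5 * max(len(region_keys), 2) + 1))
    for y, key in enumerate(region_keys):
        sub = table[(table["species"] == key[0]) & (table["focal_locus"] == key[1])]
        for row in sub.itertuples(index=False):
            face = "black" if row.is_focal else colors[row.label]
            ax.barh(
                y, row.length_bp, left=row.offset_bp, height=0.6,
                color=face, edgecolor="black", linewidth=0.5,
            )
        ax.text(
            float(sub["offset_bp"].min()), y + 0.45, f"{key[0]} ({key[1]})",
            fontsize=7, va="bottom",
        )
    ax.set_yticks([])
    ax.set_xlabel("offset from focal gene start (bp)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
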