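"""Seeded synthetic inputs with known ground truth for every pipeline stage.

Three generators stand in for the study's downloaded proteomes and genomes:

* grouped alignments with *planted* subfamily-discriminating columns —
  each group carries its own planted residue at a stated within-group
  conservation, while background columns share one modal residue across
  both groups, so false-positive discriminating-residue calls are
  measurable against a null;
* annotated genomes with a focal gene, core neighbourhood arCOGs retained
  with stated probabilities inside the fixed-flank window, an optional
  contiguous type IV pilus cassette adjacent to the focal gene in carrier
  species, and background genes whose arCOGs never collide with planted
  ids;
* species presence/phenotype tables constructed so that the co-occurrence
  tally reproduces planted counts exactly.

Two "study" wrappers lay out genome sets whose planted occurrence/presence
structure mirrors the published cetZ1 (20-region) and cetZ2 (22-region)
surveys, so region tallies and the pili-associated split can be recomputed
end to end through the real pipeline.

All generators are bit-reproducible given (spec, seed). No sequence
evolution is modelled: columns are i.i.d. draws, not tree-structured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .consensus import ChemistryClasses, UniqueResidueCall, build_consensus
from .cooccurrence import VennTally
from .io_formats import (
    STANDARD_AA,
    AlignedRecord,
    ArcogAssignment,
    Contig,
    GeneFeature,
    GenomeAnnotation,
    GroupedAlignment,
    SpeciesPhenotypeRecord,
)
from .neighborhoods import PILB_ARCOG, PILC_ARCOG, DEFAULT_PILIN_ARCOGS

_AA = np.array(list(STANDARD_AA))

#: default cassette layout: ATPase + platform anchors followed by seven
#: predicted pilins, the composition typical of CetZ2-adjacent regions
DEFAULT_CASSETTE = (PILB_ARCOG, PILC_ARCOG) + DEFAULT_PILIN_ARCOGS

#: the cetZ family's own orthologous group
CETZ_ARCOG = "arCOG02202"


# ---------------------------------------------------------------------------
# Grouped-alignment simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedColumn:
    """Ground truth for one discriminating column (0-based)."""

    column: int
    residue_a: str
    residue_b: str
    conservation_a: float = 1.0
    conservation_b: float = 1.0

    def __post_init__(self) -> None:
        if self.residue_a == self.residue_b:
            raise ValueError("planted residues must differ between groups")
        for p in (self.conservation_a, self.conservation_b):
            if not 0 <= p <= 1:
                raise ValueError("conservation must be in [0, 1]")

    def chemistry_relation(self, chemistry: ChemistryClasses | None = None) -> str:
        return (chemistry or ChemistryClasses.default()).relation(
            self.residue_a, self.residue_b
        )


@dataclass(frozen=True)
class AlignmentSimSpec:
    """Study conditions for a simulated two-group alignment.

    Defaults mirror the subfamily survey scale: 49 + 41 sequences over 350
    columns, fully conserved planted columns over a 50%-conserved background.
    """

    n_a: int = 49
    n_b: int = 41
    length: int = 350
    planted_columns: tuple[PlantedColumn, ...] = ()
    background_conservation: float = 0.5
    gap_rate: float = 0.0
    group_a: str = "A"
    group_b: str = "B"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_a < 1 or self.n_b < 1 or self.length < 1:
            raise ValueError("group sizes and length must be positive")
        cols = [p.column for p in self.planted_columns]
        if len(set(cols)) != len(cols):
            raise ValueError("planted columns must be distinct")
        if cols and not (0 <= min(cols) and max(cols) < self.length):
            raise ValueError("planted columns must lie within the alignment")
        for p in (self.background_conservation, self.gap_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.group_a == self.group_b:
            raise ValueError("group labels must differ")


def plant_discriminating_columns(
    n_different: int,
    n_similar: int,
    length: int,
    seed: int,
    conservation: float = 1.0,
    chemistry: ChemistryClasses | None = None,
) -> tuple[PlantedColumn, ...]:
    """Choose distinct columns and residue pairs with the requested chemistry mix."""
    chemistry = chemistry or ChemistryClasses.default()
    rng = np.random.default_rng(seed)
    n = n_different + n_similar
    if n > length:
        raise ValueError("more planted columns than alignment columns")
    columns = sorted(rng.choice(length, size=n, replace=False).tolist())
    aa = list(STANDARD_AA)
    similar_pairs = [
        (x, y) for x in aa for y in aa if x < y and chemistry.relation(x, y) == "similar"
    ]
    different_pairs = [
        (x, y) for x in aa for y in aa if x < y and chemistry.relation(x, y) == "different"
    ]
    planted = []
    for i, col in enumerate(columns):
        pool = different_pairs if i < n_different else similar_pairs
        ra, rb = pool[int(rng.integers(len(pool)))]
        if rng.random() < 0.5:
            ra, rb = rb, ra
        planted.append(PlantedColumn(col, ra, rb, conservation, conservation))
    return tuple(planted)


def _fill_group(
    rng: np.random.Generator, n: int, length: int, modal: np.ndarray, conservation: np.ndarray
) -> np.ndarray:
    """(n, length) residue matrix: modal residue w.p. conservation, else another."""
    keep = rng.random((n, length)) < conservation[None, :]
    out = np.broadcast_to(modal[None, :], (n, length)).copy()
    n_other = (~keep).sum()
    if n_other:
        # uniform over the 19 non-modal residues via rejection-free shifting
        modal_idx = np.searchsorted(_AA, modal)
        draws = rng.integers(0, 19, size=(n, length))
        shifted = draws + (draws >= modal_idx[None, :])
        out[~keep] = _AA[shifted[~keep]]
    return out


def simulate_subfamily_alignment(
    spec: AlignmentSimSpec,
) -> tuple[GroupedAlignment, tuple[PlantedColumn, ...]]:
    """Simulate the grouped alignment; returns it with its planted ground truth."""
    rng = np.random.default_rng(spec.seed)
    modal_a = rng.choice(_AA, size=spec.length)
    modal_b = modal_a.copy()  # background columns share the modal residue
    cons_a = np.full(spec.length, spec.background_conservation)
    cons_b = cons_a.copy()
    for p in spec.planted_columns:
        modal_a[p.column] = p.residue_a
        modal_b[p.column] = p.residue_b
        cons_a[p.column] = p.conservation_a
        cons_b[p.column] = p.conservation_b

    mat_a = _fill_group(rng, spec.n_a, spec.length, modal_a, cons_a)
    mat_b = _fill_group(rng, spec.n_b, spec.length, modal_b, cons_b)
    mat = np.vstack([mat_a, mat_b])
    if spec.gap_rate > 0:
        mat[rng.random(mat.shape) < spec.gap_rate] = "-"

    width = len(str(spec.n_a + spec.n_b))
    records = []
    for i in range(spec.n_a + spec.n_b):
        group = spec.group_a if i < spec.n_a else spec.group_b
        j = i if i < spec.n_a else i - spec.n_a
        records.append(
            AlignedRecord(f"{group}_{j:0{width}d}", group, "".join(mat[i]))
        )
    return GroupedAlignment(tuple(records)), spec.planted_columns


def simulate_query_sequence(
    alignment: GroupedAlignment,
    calls: Sequence[UniqueResidueCall],
    n_shared_with_a: int,
    query_id: str = "query",
    group_label: str = "query",
    seed: int = 0,
) -> GroupedAlignment:
    """Append a query that matches side-a consensus at exactly *n_shared_with_a*
    of the discriminating columns (and side b at the rest).

    The query backbone is the group-a consensus, so it emulates a divergent
    homologue whose affiliation is read off its discriminating positions.
    """
    if not 0 <= n_shared_with_a <= len(calls):
        raise ValueError("n_shared_with_a out of range")
    rng = np.random.default_rng(seed)
    group_a = alignment.records[0].group_label
    profile = build_consensus(alignment, group_a)
    backbone = [c.residue if c.residue else "-" for c in profile.columns]
    share = set(
        rng.choice(len(calls), size=n_shared_with_a, replace=False).tolist()
    )
    for i, call in enumerate(calls):
        backbone[call.column] = call.residue_a if i in share else call.residue_b
    query = AlignedRecord(query_id, group_label, "".join(backbone))
    return GroupedAlignment(alignment.records + (query,))


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSimSpec:
    """Study conditions for a set of simulated annotated genomes.

    Each genome carries one focal gene; each core-pool arCOG is placed
    inside the flank window with its retention probability; the cassette is
    inserted contiguously adjacent to the focal gene in carrier species
    (chosen by probability, or exactly *n_cassette_carriers* when set);
    background genes carry ids disjoint from every planted id.
    """

    n_species: int = 20
    focal_arcog: str = CETZ_ARCOG
    core_pool: tuple[tuple[str, float], ...] = ()
    #: shared low-retention arCOGs; placed like core genes but not ground truth
    background_pool: tuple[tuple[str, float], ...] = ()
    cassette: tuple[str, ...] = DEFAULT_CASSETTE
    cassette_insertion_prob: float = 0.0
    n_cassette_carriers: int | None = None
    cassette_adjacent: bool = True  # False plants the cassette far from the focal gene
    n_background_genes: int = 6
    gene_length_range: tuple[int, int] = (500, 900)
    intergenic_range: tuple[int, int] = (50, 200)
    contig_length: int = 400_000
    circular_fraction: float = 0.0
    flank_bp: int = 20_000
    extra_window_arcogs: tuple[tuple[str, ...], ...] | None = None  # per species
    offsite_arcogs: tuple[str, ...] = ()  # planted far from the focal window
    offsite_with_regulon: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be positive")
        for _, p in self.core_pool + self.background_pool:
            if not 0 <= p <= 1:
                raise ValueError("retention probabilities must be in [0, 1]")
        planted = {a for a, _ in self.core_pool}
        if planted & set(self.cassette) or planted & {a for a, _ in self.background_pool}:
            raise ValueError("core, cassette and background arCOG ids must be disjoint")
        if not 0 <= self.cassette_insertion_prob <= 1:
            raise ValueError("cassette_insertion_prob must be in [0, 1]")
        if not 0 <= self.circular_fraction <= 1:
            raise ValueError("circular_fraction must be in [0, 1]")
        if self.n_cassette_carriers is not None and not (
            0 <= self.n_cassette_carriers <= self.n_species
        ):
            raise ValueError("n_cassette_carriers out of range")
        if self.extra_window_arcogs is not None and len(self.extra_window_arcogs) != self.n_species:
            raise ValueError("extra_window_arcogs must give one tuple per species")
        if self.contig_length < 2 * self.flank_bp + self.gene_length_range[1]:
            raise ValueError("contig too short to hold a neighbourhood region")


@dataclass(frozen=True)
class SimulatedGenome:
    species: str
    annotation: GenomeAnnotation
    assignments: tuple[ArcogAssignment, ...]
    focal_locus: str


@dataclass(frozen=True)
class SimulatedGenomeSet:
    genomes: tuple[SimulatedGenome, ...]
    core_arcogs: frozenset[str]
    cassette_carriers: frozenset[str]
    #: planted window arCOG content per species (with multiplicity, incl. focal)
    window_arcogs: dict[str, tuple[str, ...]] = field(default_factory=dict)


def _place_gene(start: int, length: int, contig_len: int, circular: bool) -> tuple[int, int]:
    """Map an unwrapped start to 1-based coordinates; a gene that would span the
    circular origin is shifted to begin at base 1 (features cannot wrap)."""
    if circular:
        start = (start - 1) % contig_len + 1
        if start + length - 1 > contig_len:
            start = 1
    return start, start + length - 1


def simulate_genomes(spec: GenomeSimSpec) -> SimulatedGenomeSet:
    """Generate annotated genomes with planted neighbourhood structure."""
    rng = np.random.default_rng(spec.seed)
    if spec.n_cassette_carriers is not None:
        order = rng.permutation(spec.n_species)
        carriers_idx = set(order[: spec.n_cassette_carriers].tolist())
    else:
        carriers_idx = {
            i for i in range(spec.n_species) if rng.random() < spec.cassette_insertion_prob
        }

    genomes = []
    window_arcogs: dict[str, tuple[str, ...]] = {}
    carriers: list[str] = []
    for i in range(spec.n_species):
        species = f"species_{i:03d}"
        grng = np.random.default_rng([spec.seed, i])
        is_circular = grng.random() < spec.circular_fraction
        is_carrier = i in carriers_idx

        retained = [a for a, p in spec.core_pool if grng.random() < p]
        retained += [a for a, p in spec.background_pool if grng.random() < p]
        extras = list(spec.extra_window_arcogs[i]) if spec.extra_window_arcogs else []
        privates = [f"arCOG9x{i:03d}{j:02d}" for j in range(spec.n_background_genes)]
        loose = retained + extras + privates
        sides = grng.integers(0, 2, size=len(loose))
        left = [a for a, s in zip(loose, sides) if s == 0]
        right = [a for a, s in zip(loose, sides) if s == 1]
        grng.shuffle(left)
        grng.shuffle(right)
        cassette_here = list(spec.cassette) if (is_carrier and spec.cassette_adjacent) else []
        # cassette sits immediately adjacent to the focal gene, innermost
        right = cassette_here + right

        lo, hi = spec.gene_length_range
        glo, ghi = spec.intergenic_range
        L = spec.contig_length
        focal_len = int(grng.integers(lo, hi + 1))
        if is_circular:
            focal_start = int(grng.integers(1, L - focal_len + 1))
        else:
            focal_start = int(
                grng.integers(spec.flank_bp + 1, L - spec.flank_bp - focal_len)
            )
        focal_end = focal_start + focal_len - 1

        placed: list[tuple[str, int, int]] = []  # (arcog, start, end) unwrapped-ish
        # leftward from the focal start
        cursor = focal_start
        used = 0
        for arcog in left:
            gap = int(grng.integers(glo, ghi + 1))
            length = int(grng.integers(lo, hi + 1))
            used += gap + length
            if used > spec.flank_bp:
                raise ValueError(f"{species}: region capacity exceeded on left flank")
            start = cursor - gap - length
            placed.append((arcog, start, length))
            cursor = start
        # rightward from the focal end
        cursor = focal_end
        used = 0
        for arcog in right:
            gap = int(grng.integers(glo, ghi + 1))
            length = int(grng.integers(lo, hi + 1))
            used += gap + length
            if used > spec.flank_bp:
                raise ValueError(f"{species}: region capacity exceeded on right flank")
            start = cursor + gap + 1
            placed.append((arcog, start, length))
            cursor = start + length - 1

        features = []
        assignments = []
        focal_locus = f"{species}_g0000"
        fstart, fend = _place_gene(focal_start, focal_len, L, is_circular)
        strand = "+" if grng.random() < 0.5 else "-"
        features.append(GeneFeature("chr", fstart, fend, strand, focal_locus))
        assignments.append(
            ArcogAssignment(focal_locus, spec.focal_arcog, "D", "tubulin/FtsZ family")
        )
        gid = 1
        for arcog, start, length in placed:
            if not is_circular and (start < 1 or start + length - 1 > L):
                continue  # clipped off a linear contig edge
            gstart, gend = _place_gene(start, length, L, is_circular)
            locus = f"{species}_g{gid:04d}"
            gid += 1
            strand = "+" if grng.random() < 0.5 else "-"
            features.append(GeneFeature("chr", gstart, gend, strand, locus))
            assignments.append(ArcogAssignment(locus, arcog))

        # far-field content: distant background, plus optional offsite targets
        far_anchor = (focal_start + L // 2 - 1) % L + 1
        cursor = far_anchor
        far = [f"arCOG9y{i:03d}{j}" for j in range(3)] + list(spec.offsite_arcogs)
        if spec.offsite_with_regulon and spec.offsite_arcogs:
            far += [PILB_ARCOG, PILC_ARCOG]
        if is_carrier and not spec.cassette_adjacent:
            far += list(spec.cassette)
        for arcog in far:
            gap = int(grng.integers(glo, ghi + 1))
            length = int(grng.integers(lo, hi + 1))
            gstart, gend = _place_gene(cursor + gap + 1, length, L, is_circular)
            if gend > L:
                break
            locus = f"{species}_g{gid:04d}"
            gid += 1
            strand = "+" if grng.random() < 0.5 else "-"
            features.append(GeneFeature("chr", gstart, gend, strand, locus))
            assignments.append(ArcogAssignment(locus, arcog))
            cursor = gend

        annotation = GenomeAnnotation(
            (Contig("chr", L, is_circular),), tuple(features)
        )
        genomes.append(
            SimulatedGenome(species, annotation, tuple(assignments), focal_locus)
        )
        window_arcogs[species] = tuple(
            [spec.focal_arcog] + cassette_here + left + [a for a in right if a not in cassette_here]
        )
        if is_carrier:
            carriers.append(species)

    return SimulatedGenomeSet(
        genomes=tuple(genomes),
        core_arcogs=frozenset(a for a, _ in spec.core_pool),
        cassette_carriers=frozenset(carriers),
        window_arcogs=window_arcogs,
    )


# ---------------------------------------------------------------------------
# Published-survey-shaped genome sets
# ---------------------------------------------------------------------------


def _pick(rng: np.random.Generator, n: int, k: int) -> set[int]:
    return set(rng.permutation(n)[:k].tolist())


def simulate_cetz1_study(seed: int = 0, flank_bp: int = 20_000) -> SimulatedGenomeSet:
    """A 20-genome set shaped like the cetZ1 neighbourhood survey.

    Planted structure: a second cetZ-family gene inside 2 of the 20 windows
    (so the family arCOG occurs 22 times over 20 regions); paired Lrp/AsnC
    transcriptional-regulator genes (arCOG01117) in 11 regions and a single
    copy in 4 more (26 occurrences, 15-region presence), with the potassium
    transporter arCOG01957 in 12 of the regulator-bearing regions; and the
    sugar-epimerase gene arCOG03015 in all 20 regions.
    """
    rng = np.random.default_rng([seed, 1])
    n = 20
    extra_cetz = _pick(rng, n, 2)
    regulators = rng.permutation(n)[:15].tolist()
    paired = set(regulators[:11])
    single = set(regulators[11:])
    potassium = set(np.array(regulators)[rng.permutation(15)[:12]].tolist())
    extras: list[tuple[str, ...]] = []
    for i in range(n):
        e: list[str] = []
        if i in extra_cetz:
            e.append(CETZ_ARCOG)
        if i in paired:
            e += ["arCOG01117", "arCOG01117"]
        elif i in single:
            e.append("arCOG01117")
        if i in potassium:
            e.append("arCOG01957")
        e.append("arCOG03015")
        extras.append(tuple(e))
    spec = GenomeSimSpec(
        n_species=n,
        core_pool=(),
        cassette_insertion_prob=0.0,
        extra_window_arcogs=tuple(extras),
        flank_bp=flank_bp,
        circular_fraction=0.25,
        seed=seed,
    )
    simset = simulate_genomes(spec)
    return SimulatedGenomeSet(
        genomes=simset.genomes,
        core_arcogs=frozenset({"arCOG01117", "arCOG03015"}),
        cassette_carriers=frozenset(),
        window_arcogs=simset.window_arcogs,
    )


def simulate_cetz2_study(seed: int = 0, flank_bp: int = 20_000) -> SimulatedGenomeSet:
    """A 22-genome set shaped like the cetZ2 neighbourhood survey.

    Planted structure: one window carries an additional cetZ-family gene (23
    family-arCOG occurrences over 22 regions); the type IV pilus cassette is
    planted adjacent to the focal gene in exactly 12 genomes (a 12/10
    pili-associated split); and the near-universal companions arCOG04674
    (putative transcription factor) and arCOG03095 (sugar epimerase) appear
    in 20 and 19 windows respectively.
    """
    rng = np.random.default_rng([seed, 2])
    n = 22
    extra_cetz = _pick(rng, n, 1)
    tf = _pick(rng, n, 20)
    epimerase = _pick(rng, n, 19)
    extras = []
    for i in range(n):
        e = []
        if i in extra_cetz:
            e.append(CETZ_ARCOG)
        if i in tf:
            e.append("arCOG04674")
        if i in epimerase:
            e.append("arCOG03095")
        extras.append(tuple(e))
    spec = GenomeSimSpec(
        n_species=n,
        n_cassette_carriers=12,
        extra_window_arcogs=tuple(extras),
        flank_bp=flank_bp,
        circular_fraction=0.25,
        seed=seed,
    )
    return simulate_genomes(spec)


# ---------------------------------------------------------------------------
# Species-table simulation
# ---------------------------------------------------------------------------

_ORDERS = ("Haloferacales", "Halobacteriales", "Natrialbales")


def simulate_species_table(
    planted: VennTally, seed: int = 0
) -> list[SpeciesPhenotypeRecord]:
    """Construct a species table whose co-occurrence tally equals *planted* exactly.

    Rod and motility reports beyond the planted both/CetZ1-only conditionals
    are assigned to CetZ2-only then no-CetZ species (overlapping where
    possible); the construction errors out if the planted counts cannot be
    realised. Record order is shuffled by *seed* — tallies are order-free.
    """
    leftover_rod = planted.n_rod - planted.n_rod_and_both - planted.n_rod_and_cetz1_only
    leftover_mot = (
        planted.n_motile - planted.n_motile_and_both - planted.n_motile_and_cetz1_only
    )
    pool = planted.n_cetz2_only + planted.n_neither
    if leftover_rod < 0 or leftover_mot < 0:
        raise ValueError("conditional counts exceed their marginals")
    if leftover_rod > pool or leftover_mot > pool:
        raise ValueError("rod/motility counts cannot be realised outside both/CetZ1-only")

    rng = np.random.default_rng(seed)
    rows: list[tuple[bool, bool, bool, bool]] = []  # cetz1, cetz2, motile, rod

    def emit(count, cetz1, cetz2, motile_first, rod_first):
        for j in range(count):
            rows.append((cetz1, cetz2, j < motile_first, j < rod_first))

    emit(planted.n_both, True, True, planted.n_motile_and_both, planted.n_rod_and_both)
    emit(
        planted.n_cetz1_only, True, False,
        planted.n_motile_and_cetz1_only, planted.n_rod_and_cetz1_only,
    )
    emit(planted.n_cetz2_only, False, True, 0, 0)
    emit(planted.n_neither, False, False, 0, 0)
    # distribute leftover reports over the cetz2-only + neither block, front first
    # so rod and motility overlap in the same species where both remain
    base = planted.n_both + planted.n_cetz1_only
    for j in range(leftover_mot):
        c1, c2, _, rod = rows[base + j]
        rows[base + j] = (c1, c2, True, rod)
    for j in range(leftover_rod):
        c1, c2, mot, _ = rows[base + j]
        rows[base + j] = (c1, c2, mot, True)

    order = rng.permutation(len(rows))
    records = []
    for rank, idx in enumerate(order):
        c1, c2, mot, rod = rows[idx]
        records.append(
            SpeciesPhenotypeRecord(
                species=f"species_{rank:03d}",
                taxon_order=_ORDERS[rank % len(_ORDERS)],
                has_cetz1=c1,
                has_cetz2=c2,
                n_other_cetz=int(rng.integers(0, 5)),
                motility_reported=mot,
                rods_reported=rod,
            )
        )
    return records


#: the published 55-species Halobacteria survey counts, usable as a fixture
SURVEY_VENN = VennTally(
    n_species=55,
    n_both=45,
    n_cetz1_only=7,
    n_cetz2_only=0,
    n_neither=3,
    n_motile=26,
    n_motile_and_both=24,
    n_motile_and_cetz1_only=1,
    n_rod=40,
    n_rod_and_both=37,
    n_rod_and_cetz1_only=2,
)
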