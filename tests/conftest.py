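"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's vectorized code paths: they
enumerate columns/intervals directly with plain Python counting, so the
implementation and its check share no code.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from cetzkit.io_formats import (
    STANDARD_AA,
    AlignedRecord,
    Contig,
    GeneFeature,
    GenomeAnnotation,
    GroupedAlignment,
)

# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------


def consensus_oracle(alignment: GroupedAlignment, group: str):
    """Per-column (residue, score, gap_fraction, depth) by direct counting."""
    members = [r.gapped_sequence for r in alignment.records if r.group_label == group]
    out = []
    for c in range(alignment.length):
        chars = [s[c] for s in members]
        gaps = chars.count("-")
        depth = len(chars) - gaps
        counts = Counter(ch for ch in chars if ch in STANDARD_AA)
        if depth == 0 or not counts:
            out.append((None, 0.0, gaps / len(chars), depth))
            continue
        best = max(counts.values())
        residue = min(r for r, n in counts.items() if n == best)  # alphabetical tie-break
        out.append((residue, 100.0 * best / depth, gaps / len(chars), depth))
    return out


def window_members_oracle(
    annotation: GenomeAnnotation, focal_locus: str, flank_bp: int
) -> set[str]:
    """Loci overlapping the window, by doubled-sequence scan on circular contigs."""
    focal = annotation.feature(focal_locus)
    contig = annotation.contig(focal.contig_id)
    L = contig.length_bp
    feats = [f for f in annotation.features if f.contig_id == contig.contig_id]
    if not contig.is_circular:
        lo = max(1, focal.start_bp - flank_bp)
        hi = min(L, focal.end_bp + flank_bp)
        return {f.locus_id for f in feats if f.start_bp <= hi and f.end_bp >= lo}
    # unrolled sequence: every feature appears at its position and at +L and
    # +2L; the window is taken around the focal copy at +L so it never clips
    # (its right edge may pass 2L when the flank approaches the contig length)
    doubled = [
        (f.locus_id, f.start_bp + k * L, f.end_bp + k * L)
        for f in feats
        for k in (0, 1, 2)
    ]
    lo = focal.start_bp + L - flank_bp
    hi = focal.end_bp + L + flank_bp
    if hi - lo + 1 >= L:  # window covers the whole circle
        return {f.locus_id for f in feats}
    return {locus for locus, s, e in doubled if s <= hi and e >= lo}


def random_alignment(
    rng: np.random.Generator,
    n_a: int,
    n_b: int,
    length: int,
    gap_rate: float = 0.1,
    ambiguity_rate: float = 0.02,
) -> GroupedAlignment:
    alphabet = list(STANDARD_AA)
    records = []
    for g, n in (("A", n_a), ("B", n_b)):
        for i in range(n):
            chars = rng.choice(alphabet, size=length)
            mask = rng.random(length) < gap_rate
            chars[mask] = "-"
            amb = rng.random(length) < ambiguity_rate
            chars[amb] = rng.choice(["X", "B", "Z"], size=int(amb.sum()))
            records.append(AlignedRecord(f"{g}{i}", g, "".join(chars)))
    return GroupedAlignment(tuple(records))


def random_annotation(rng: np.random.Generator) -> tuple[GenomeAnnotation, str, int]:
    """A random single-contig genome; returns (annotation, focal locus, flank)."""
    L = int(rng.integers(50_000, 150_000))
    circular = bool(rng.random() < 0.5)
    n_genes = int(rng.integers(10, 40))
    features = []
    for i in range(n_genes):
        length = int(rng.integers(200, 2_000))
        start = int(rng.integers(1, L - length))
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(GeneFeature("c1", start, start + length - 1, strand, f"g{i}"))
    annotation = GenomeAnnotation((Contig("c1", L, circular),), tuple(features))
    focal = features[int(rng.integers(n_genes))].locus_id
    flank = int(rng.integers(5_000, 25_000))
    return annotation, focal, flank


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def tiny_alignment() -> GroupedAlignment:
    """Two groups of two; column 0 discriminates (D vs K), column 4 is gapped."""
    return GroupedAlignment(
        (
            AlignedRecord("a1", "A", "DAGLC"),
            AlignedRecord("a2", "A", "DAGIC"),
            AlignedRecord("b1", "B", "KAGL-"),
            AlignedRecord("b2", "B", "KAGL-"),
        )
    )


@pytest.fixture
def linear_genome() -> GenomeAnnotation:
    features = (
        GeneFeature("c1", 100_000, 101_000, "+", "focal"),
        GeneFeature("c1", 85_000, 86_000, "+", "left_in"),
        GeneFeature("c1", 79_500, 80_500, "-", "left_edge"),  # partial overlap
        GeneFeature("c1", 120_500, 121_500, "+", "right_edge"),
        GeneFeature("c1", 50_000, 51_000, "+", "far_left"),
        GeneFeature("c1", 200_000, 201_000, "-", "far_right"),
    )
    return GenomeAnnotation((Contig("c1", 3_000_000, False),), features)
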