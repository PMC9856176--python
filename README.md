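# cetzkit

Tools for characterizing archaeal CetZ tubulin-superfamily proteins: which
alignment positions discriminate the CetZ1 and CetZ2 subfamilies, which
orthologous groups are conserved in the genomic neighbourhood of *cetZ*
genes, whether a *cetZ* gene sits next to a type IV pilus regulon, and how
CetZ subfamily presence co-occurs with reported motility and rod-shape
phenotypes across species.

CetZs are the third, archaea-specific family of the tubulin superfamily
(alongside tubulin and FtsZ), implicated in cell-shape control and
motility in Halobacteria. `cetzkit` packages the comparative-genomic
computations used to characterize them, for anyone asking the same
questions of their own alignments and genome annotations.

## The statistics

**Unique residue score.** Given a joint multiple sequence alignment whose
rows are labelled with subfamily groups, each group *g* gets a per-column
consensus: the modal residue *r<sub>g</sub>(c)* among non-gap characters,
and its consensus score

&nbsp;&nbsp;&nbsp;&nbsp;*S<sub>g</sub>(c)* = 100 · #{sequences in *g* with *r<sub>g</sub>(c)* at *c*} / #{non-gap characters of *g* at *c*}.

For two groups *a*, *b* the **unique residue score** at column *c* is the
mean (*S<sub>a</sub>(c)* + *S<sub>b</sub>(c)*) / 2. A column is called a
*unique residue* when the consensus residues differ and the score exceeds
a threshold — 90% for the CetZ1-vs-CetZ2 comparison, 80% at the
FtsZ-vs-CetZ family level. Calls are labelled by whether the two residues
share a side-chain chemistry class (nonpolar / aromatic / polar-uncharged
/ positive / negative; overridable). A query sequence can be scored by how
many discriminating positions it shares with each group's consensus, and
ungapped span lengths profile loop regions such as the M-loop (long in
CetZ1-like, short in CetZ2-like proteins).

**Neighbourhood conservation.** Around each focal gene a fixed-flank
window (20 kb either side by default, truncated at linear contig ends and
wrapped across circular origins) is extracted; member genes are labelled
with arCOG ids and tallied across species as *occurrences* (gene count)
and *presence* (regions containing the arCOG). arCOGs present in at least
a chosen number of regions (default: a majority) are the conserved set,
drawn as focal-gene-oriented synteny maps. A region is *pili-associated*
when it contains a run of type IV pilus regulon genes — anchored by
distinct pilB/pilC arCOGs, interrupted by at most a few non-regulon
genes — and a target arCOG's genome-wide placement is classified as
in-region, elsewhere-with-regulon, elsewhere-alone, or absent.

**Co-occurrence.** Species tables of CetZ1/CetZ2 presence and reported
phenotypes are tallied as Venn-style counts; absence of a report is never
treated as a negative.

Because the original surveys' inputs are whole downloaded proteomes and
genomes, `cetzkit` ships seeded synthetic generators that emulate every
input with planted ground truth (discriminating columns, conserved core
arCOGs, pilus cassettes, co-occurrence counts), so the whole pipeline is
testable at desk scale.

## Worked example

```python
from cetzkit import (build_consensus, unique_residue_scores, call_unique_residues,
                     tally_arcogs, classify_pili_association,
                     extract_neighborhood, annotate_region)
from cetzkit.synthetic_data import (AlignmentSimSpec, plant_discriminating_columns,
                                    simulate_subfamily_alignment, simulate_cetz2_study)

# a survey-scale alignment: 49 + 41 sequences, 26 planted discriminating columns
planted = plant_discriminating_columns(n_different=10, n_similar=16, length=350, seed=5)
aln, truth = simulate_subfamily_alignment(
    AlignmentSimSpec(n_a=49, n_b=41, length=350, planted_columns=planted,
                     group_a="CetZ1", group_b="CetZ2", seed=7))
table = unique_residue_scores(build_consensus(aln, "CetZ1"), build_consensus(aln, "CetZ2"))
calls = call_unique_residues(table, threshold_pct=90)
print(f"{len(calls)} unique residues "
      f"({sum(c.chemistry == 'different' for c in calls)} different chemistry, "
      f"{sum(c.chemistry == 'similar' for c in calls)} similar)")

# a 22-genome cetZ2-style region survey
study = simulate_cetz2_study(seed=3)
regions = [annotate_region(extract_neighborhood(g.annotation, g.focal_locus, 20_000,
                                                species=g.species), g.assignments)
           for g in study.genomes]
tally = tally_arcogs(regions)
n_pili = sum(classify_pili_association(r)[0] for r in regions)
print(f"{tally.n_regions} regions; cetZ arCOG seen {tally.occurrences['arCOG02202']} times; "
      f"{n_pili} pili-associated, {tally.n_regions - n_pili} not")
```

prints

```
26 unique residues (10 different chemistry, 16 similar)
22 regions; cetZ arCOG seen 23 times; 12 pili-associated, 10 not
```

The 26 calls are exactly the planted columns — the discriminating-residue
statistic at threshold 90 separates fully conserved subfamily differences
from a 50%-conserved background without false positives at this scale. In
the region survey, the cetZ-family arCOG (arCOG02202) is counted 23 times
across 22 regions because one window contains a second cetZ gene, and the
pilus-cassette classifier splits the regions 12 / 10, matching the planted
carriers.

The same analyses run from the shell via the `cetz` CLI
(`cetz simulate | consensus | neighborhoods | conserved | pili | venn | run`);
`cetz run --config config.yaml --out out/` executes every analysis the
config provides inputs for and writes a manifest plus self-describing TSVs.

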