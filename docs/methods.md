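# Methods

## Scope and model

`cetzkit` implements four linked comparative-genomic procedures around the
archaeal CetZ tubulin-superfamily proteins:

1. consensus-based discrimination of subfamilies in a grouped multiple
   sequence alignment (the *unique residue score*);
2. fixed-flank gene-neighbourhood extraction and cross-species arCOG
   occurrence/presence tallies with a conserved-set call and synteny maps;
3. type IV pilus regulon detection within a neighbourhood and genome-wide
   placement of a target arCOG relative to the focal region;
4. species-level co-occurrence tallies of CetZ1/CetZ2 presence against
   reported motility and rod-shape phenotypes.

A seeded synthetic-data module generates every input with planted ground
truth, so each procedure is validated by exact recovery rather than by
inspection.

## Consensus profiles and unique residues

For a group *g* and column *c*, the consensus residue is the modal
standard amino acid among non-gap characters, and the consensus score is
100 × (modal count) / (non-gap count). Definitional choices:

* **Joint alignment.** The two groups live in one alignment with row
  labels, not two separately built alignments. Comparing columns across
  two independent alignments is ill-defined without a column mapping; a
  joint alignment is the minimal well-defined equivalent, and group labels
  are free strings so nothing is specific to CetZ1/CetZ2.
* **Gaps** are excluded from numerator and denominator of the score.
  Columns where either group is majority-gap (gap fraction > 0.5,
  configurable via `max_gap_fraction`) are excluded from calling: they
  have no meaningful consensus.
* **Ambiguity codes** X/B/Z count toward depth but can never be the
  consensus residue — they are not chemistry-classifiable.
* **Ties** on the modal residue break alphabetically and are flagged
  (`tie=True`) so downstream users can treat tied columns specially.
* The **threshold** ("score greater than 90%") is a strict inequality by
  default (`strict=True`); ≥ is available. A call additionally requires
  the two consensus residues to differ — that is what makes the column
  *unique* to a subfamily; the score alone does not.
* **Chemistry classes** default to a five-class scheme — nonpolar
  {G,A,V,L,I,M,P}, aromatic {F,W,Y}, polar-uncharged {S,T,C,N,Q}, positive
  {K,R,H}, negative {D,E} — and are user-overridable via a TSV, since
  chemistry colourings vary between sources. Reported chemistry splits
  therefore depend on the chosen scheme.

Query affiliation (`shared_unique_residues`) counts, over a call set, the
positions where a query row equals one side's consensus residue; a gap
never matches. Loop-region profiling (`region_lengths`) reports ungapped
span lengths per sequence with per-group min/median/max — long M-loops
(~14–26 residues) versus short ones (~3–6) separate CetZ1-like from
CetZ2-like sequences.

## Neighbourhood windows

The window around a focal gene spans `focal.start − flank` through
`focal.end + flank` (default flank 20 kb, hence ~40 kb regions). Flank is
measured from the gene boundaries, not the midpoint, matching the "20 kb
on either side of the gene" reading. Windows truncate at linear contig
ends and wrap across the origin of circular contigs (represented as two
intervals); circularity is declared in configuration, never guessed from
annotation. Genes partially overlapping the window are included whole —
the tallies count genes, not base pairs. Members carry window-local
offsets (wrap already resolved) so ordering and synteny offsets are
topology-independent. All coordinates are 1-based inclusive throughout;
any half-open arithmetic is internal.

Occurrences (total gene count) and presence (regions containing ≥ 1 copy)
are kept as two statistics because both are informative: a region with a
duplicated gene raises occurrences but not presence. The conserved-set
threshold defaults to ⌈n/2⌉ but is always explicit in output metadata and
accepts an absolute count, since surveys of different sizes have used a
fixed "at least 10" irrespective of majority.

## Pilus-regulon classification

A regulon definition names anchor arCOGs (default: the pilB assembly
ATPase arCOG01818 plus a pilC platform id), accessory pilin arCOGs, a
minimum number of distinct anchors (default 2) and a tolerated gene gap
(default 3). The pilC orthologous-group id is not standardised across
annotators, so the default uses the sentinel label `"pilC"`; override it
with the id your annotation source emits. Classification clusters
regulon-member genes into runs in window order, allowing up to
`max_gene_gap` intervening non-regulon genes (unassigned genes count as
interruptions — conservative cassette calling), and the region is
pili-associated iff some run contains the required distinct anchors;
`matched_loci` is the union of qualifying runs. Requiring the anchors to
share a run, rather than demanding that *every* regulon gene in the window
be contiguous, means a stray pilin elsewhere in the window cannot veto an
intact cassette. "Adjacent" has no published quantitative definition; the
run/gap rule is one defensible reading and both knobs are exposed.

Genome-wide placement of a target arCOG returns the first matching
category of: `in_focal_region`, `elsewhere_with_regulon` (a target locus
within `flank_bp` of ≥ `min_anchors` distinct anchors outside the focal
region, distance measured between gene spans, circular-aware),
`elsewhere_alone`, `absent`.

## Co-occurrence tallies

Venn tallies are direct enumerations; "reported" phenotype fields mean
exactly that — a False is "not reported", never "reported negative", so
species without reports contribute only to the marginals they satisfy. No
significance testing is attached: the counts describe a pattern and the
sample of species is not phylogenetically independent, so a naive test
would overstate the evidence.

## Synthetic data: what it emulates and what it does not

* **Alignments**: at planted columns each group carries its planted
  residue with the stated within-group conservation (replacement residues
  uniform over the other 19); background columns share one modal residue
  across both groups at `background_conservation` (default 0.5), giving a
  null against which false-positive unique-residue calls are measurable.
  Gaps are i.i.d. at `gap_rate`. Default sizes (49 + 41 sequences, 350
  columns) match the subfamily survey scale. There is no substitution
  model, no indel evolution, no phylogenetic correlation between
  sequences — so passing tests show the *statistic* behaves as defined,
  not that real subfamilies are this cleanly separated.
* **Genomes**: one focal gene per genome; core arCOGs retained in the
  window with stated probabilities; a contiguous cassette adjacent to the
  focal gene in carrier species (by probability, or an exact count for
  survey-shaped sets); background genes with ids disjoint from all
  planted ids; gene lengths uniform on 500–900 bp and intergenic gaps on
  50–200 bp (compact archaeal coding density, and guaranteeing ~20+ genes
  fit per 20 kb flank; a planted layout that cannot fit raises a capacity
  error rather than silently truncating). Contigs default to 400 kb with
  a configurable circular fraction; genes never span the circular origin
  (a gene that would is shifted to start at base 1). Real genomes have
  operonic strand structure and non-uniform spacing; none of that is
  modelled because the tallies are invariant to it.
* **Survey-shaped sets**: `simulate_cetz1_study` (20 genomes: a second
  cetZ gene in 2 windows; paired Lrp/AsnC regulators in 11 windows plus a
  single copy in 4 more; the potassium transporter in 12; the epimerase in
  all 20) and `simulate_cetz2_study` (22 genomes: one extra cetZ gene; the
  cassette in exactly 12; near-universal companion arCOGs in 20 and 19
  windows). These plant the published survey's occurrence/presence
  structure as study conditions; the pipeline then recomputes the tallies
  from the generated genomes. They stand in for the original surveys'
  species tables, which are not redistributed here.
* **Species tables** are constructed, not sampled: the requested Venn
  counts are laid out deterministically (leftover rod/motility reports go
  to CetZ2-only then no-CetZ species, overlapping where possible) and the
  row order is shuffled by seed, so the tally reproduces the planted
  counts exactly or construction fails loudly.

All generators are bit-reproducible given (spec, seed); per-genome RNG
streams are derived from (seed, species index) so genomes are independent
of each other and of set-level choices.

## Numerical and testing choices

Consensus counting is vectorized (per-column character histograms);
the test suite checks it against an independent pure-Python counting
oracle on random alignments up to 50 × 500, and window extraction against
a brute-force interval scan with circular cases checked via an unrolled
(0, +L, +2L) linear copy of the contig. Determinism is asserted end to
end: identical configs give byte-identical TSVs. Problem sizes in the
suite (hundreds of small random instances, 100-seed recovery runs of
20-genome sets) keep the full suite in a few seconds while exercising
every branch including circular wrap.

## Known limitations

* Multi-hit arCOG assignments must be resolved upstream: the reader takes
  one arCOG per locus and rejects duplicates.
* The chemistry-split of a call set is only as meaningful as the class
  scheme; with a different partition the similar/different labels move.
* Pili classification depends on annotator-consistent anchor ids; with a
  missing pilC id the default regulon can never match (by design — set it).
* The synthetic null (i.i.d. columns, uniform replacement) is harsher
  than real alignments in some ways (no covariation) and milder in others
  (no alignment error); recovery rates measured on it do not transfer
  quantitatively to real data.
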