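# Methods

## Model

`synrefine` treats a genome as an ordered list of protein-coding loci per
replicon and an orthogroup table as a labelling of those loci by homology
family (HOG). The only evidence it weighs is neighborhood content: two
same-HOG genes from different genomes are accepted as orthologs when the
homology families around them overlap sufficiently. No sequence,
phylogenetic or orientation information enters the test.

### The look-around window

For a center gene and a partner genome, the window walks outward along the
center's replicon collecting up to *w*/2 qualifying genes per side. A
neighbor qualifies only if it carries a HOG label **and** that HOG has at
least one member in the partner genome — a gene with no counterpart there
can never produce a match, so it is skipped and the window reaches one gene
further. The center itself never occupies a slot. When one side runs into a
replicon boundary, the other side is extended so the total still approaches
*w*. Windows never cross replicon boundaries and never wrap: replicons are
treated as linear even when the underlying chromosome is circular. The wrap
behavior for circular chromosomes is genuinely underdetermined by the
method's description; linear treatment matches how scaffold boundaries are
handled and is the conservative choice (a boundary can only lose signal,
never fabricate it).

### The synteny ratio

Both windows of a pair are reduced to multisets of HOG labels and matched
by multiset intersection: a HOG occurring twice in one window and once in
the other contributes one match (each window gene is usable at most once).
This min-multiplicity rule is the single most consequential interpretation
in the implementation — "matching pairs of genes" could also be read as
counting ordered hits — and was chosen because it makes the score symmetric
in the pair and bounds matches by *w* by construction. Order within the
window is deliberately ignored: local scrambling (small inversions) should
not destroy evidence of a conserved neighborhood.

The ratio is `matches / denominator`. Two denominator conventions are
provided (`truncation_mode`):

* `effective_denominator` (default): the larger of the two realised window
  sizes, capped at *w*. Near a replicon or scaffold edge fewer than *w*
  qualifying neighbors exist; dividing by the full *w* there would make it
  arithmetically impossible for edge genes to reach ratio 1, silently
  biasing against genes on short scaffolds.
* `fixed_denominator`: always *w* — the literal form of the defining
  formula, available for strict reproduction.

A pair with two empty windows has no evidence either way and is scored 0,
not syntenic.

### The decision rule

A pair is syntenic when the ratio passes `synteny_ratio_cutoff` (default
0.5). The comparison is inclusive (`>=`) by default, so the boundary case
(a ratio exactly at the cutoff, common with small windows) behaves
reproducibly and permissively; the strict `>` is available via
`cutoff_cmp="gt"`.

### SOG construction

Within a HOG, every cross-genome member pair is scored and syntenic pairs
become edges of an undirected graph on the members (edges only between
genomes; same-genome paralogs can co-cluster only transitively through a
shared cross-genome partner, which is exactly the tandem-duplicate case).
Connected components spanning at least two genomes become SOGs — a
single-genome component is not an ortholog group and its members are
excluded. SOGs are indexed deterministically by the smallest (manifest
rank, replicon, ordinal) of their members, giving stable names such as
`SOG19.0`, `SOG19.1`. Outcomes: `confirmed` — one SOG holds every analyzed
member; `unconfirmed` — no SOG; `modified` — anything between.

By default only HOGs spanning ≥ 2 genomes with at least one within-genome
paralog are analyzed (the others are reported `not_analyzed`);
`run_all_hogs` also scores the 1-per-genome HOGs, which can expose hidden
paralogy where the original copy was lost.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `window_size` (*w*) | 8 (genes) | total neighbor slots, *w*/2 per side; even, ≥ 2. 8 suits closely related genomes; 30 with cutoff 0.2 suits distant ones. Odd values are rejected to keep side symmetry well defined. |
| `synteny_ratio_cutoff` | 0.5 | matched fraction required; in (0, 1] |
| `cutoff_cmp` | `ge` | inclusive or strict comparison at the cutoff |
| `run_all_hogs` | false | also score 1-per-genome HOGs |
| `truncation_mode` | `effective_denominator` | boundary denominator convention (above) |

Lowering the cutoff (or growing the window) only adds edges, so SOGs can
only merge or grow and the confirmed count is non-decreasing — a useful
sanity property that the tests exercise.

## Input handling

Feature tables are consumed in the tab-delimited RefSeq dialect; only CDS
rows with a locus_tag form the window substrate (the homology input is a
proteome clustering, so RNA genes are invisible to the test). Multiple CDS
rows sharing a locus_tag collapse to one gene spanning the union of their
intervals. Orthogroup-table identifiers resolve to genes by product
accession, falling back to locus_tag; an accession annotated at several
loci (identical-protein records) labels all of them, and the synteny test
discriminates among the loci downstream — preferable to an arbitrary single
assignment, since multi-locus families are exactly the cases the method
exists to resolve. The genome columns of the orthogroup table are paired
with manifest lines positionally; `--map` overrides the pairing, and a
genome resolving fewer than 90 % of its identifiers triggers a loud
warning, the usual symptom of a misordered manifest.

## The synthetic generator

`simulate_dataset` descends *n* genomes from a shared ancestral gene order
through inversions (reverse a span), translocations (move a span), tandem
and dispersed duplications, and losses, tracking each gene's ancestral
family and whether its lineage passed through a duplication. Families
become the emitted orthogroups — all descendants grouped, duplicates
included — emulating an initial homology clustering that has not yet
separated paralogs. Defaults (four genomes, 100 ancestral genes, 2
inversions of span 6, 1 translocation, 3 tandem + 2 dispersed duplications,
3 losses per genome) are pitched at a congeneric bacterial comparison:
gene order largely conserved, with enough duplication to give the
refinement something to resolve. Coordinates are synthetic (gene *k* at
1000·*k* + 1, 900 bp, forward strand); a multi-replicon mode splits each
genome into contiguous chunks to exercise boundary truncation.

What the generator does **not** emulate: sequence divergence and the
resulting mis-clustering (families are labelled perfectly), horizontal
transfer, unequal genome sizes, annotation errors, and operon-scale
functional structure. Passing tests therefore demonstrate the correctness
of the window logic and the refinement's behavior under known
rearrangement — not end-to-end accuracy on real annotations, which also
depends on the upstream clustering.

The truth bookkeeping defines a cross-genome pair as a true ortholog pair
when both genes descend from the same ancestral gene with no duplication on
either lineage; precision of a grouping is the true-ortholog fraction of
its within-group cross-genome pairs, recall the fraction of true pairs
co-grouped. A grouping proposing no pairs has precision 1 by convention.

`brute_force_sr` and `brute_force_partition` re-implement the scoring and
partition contracts by exhaustive scanning (recomputing neighbor order from
start coordinates, greedy matching, hand-written union-find) with no code
shared with the main path; they are test oracles only and refuse instances
above 50 genes per genome.

## Summary statistics

HOG classes (1-to-1 / 0-or-1 / paralogous / single-genome) are computed
from the raw table row, before identifier resolution, since they describe
the upstream clustering. Outcome percentages are reported per class with
single-genome HOGs excluded (they cannot be analyzed). AMNOG — per HOG, the
maximum number of genomes represented in a paralog-free SOG, averaged over
HOGs — is reported in both plausible conventions because the inclusion set
of the average is ambiguous: `amnog_all` averages over every analyzed
multi-genome HOG (non-qualifying HOGs contribute 0), `amnog_qualifying`
restricts to HOGs with at least one paralog-free SOG. "Genomes
represented", not gene count, is the size metric, consistent with a
paralog-free SOG holding at most one gene per genome. Percentages are
rounded only at presentation; raw counts are always emitted.

## Numerical and determinism notes

There is no randomness anywhere in the core: results are independent of
HOG evaluation order, ties in SOG indexing are broken by (manifest rank,
replicon id, ordinal), and output rows are sorted deterministically, so
reruns on identical inputs are byte-identical. The generator consumes a
single seeded RNG sequentially, making datasets reproducible
byte-for-byte under a fixed seed. Test problem sizes (3–5 genomes, 30–100
genes, ≤ 20 seeded instances) keep the full suite in the seconds-to-a-
minute range while staying inside the oracle's validity bound.

## Known limitations

* Synteny erodes with evolutionary distance; beyond roughly family-level
  comparisons even the wide-window regime loses power, and the method
  should be treated as a refinement of, not a replacement for, the
  upstream clustering.
* A paralog that happens to sit in a conserved duplicated block (segmental
  duplication) passes the window test and is not removable by this
  criterion; adjacent tandem duplicates are likewise undecidable and are
  kept together in one SOG by design.
* The two directional windows of a pair are combined by one symmetric
  min-multiplicity match, so a single ratio is reported per pair;
  directional variants (scoring each window against the other separately)
  are conceivable but not provided.
* Genomes with sparse or fragmented assemblies shrink the effective
  window; the `effective_denominator` default compensates but cannot
  recover signal that is absent.
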