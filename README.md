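# mitedyn

Comparative dynamics of miniature transposable-element (MITE-like) families
across related genomes, built around the history of the *Mariam* family in
diploid and polyploid wheat.

Short non-autonomous DNA elements such as *Mariam* (~300 bp, no terminal
inverted repeats) leave two diagnostic signatures when they transpose: a
short target site duplication (TSD) at the insertion junction, and
insertional polymorphism — a locus that carries the element in one species
and is empty or missing in another. `mitedyn` turns the desk analysis of
such a family into a reusable, tested pipeline:

* **te_search** — seed-and-extend retrieval of family copies from assemblies
  (exact 12-mers chained by diagonal, gapped local extension; explicit
  identity/coverage thresholds anchored to the 80/80 family rule instead of
  a database-size-dependent E-value), with overlap deduplication and
  full/short length classification.
* **tsd_flank** — junction-anchored TSD detection in configurable flank
  windows and position-frequency-matrix summaries (sequence-logo input).
* **comparative** — presence/absence of each insertion locus in every other
  genome by reciprocal-best mapping of 1000-bp flanks, an orthologous-locus
  membership matrix, Venn region counts, and gene associations within a
  500-bp window.
* **phylo** — progressive multiple alignment, majority consensus building,
  subfamily assignment, Tamura–Nei (TN93) distances, neighbor joining, and
  column-bootstrap support with a 45% collapse option.
* **rearrangement** — chromosome walking: a growing window around a
  polymorphic locus is dot-plot matched (≥1000 bp anchors at ≥90% identity
  at paper scale; a 300-bp desk preset is included) against a counterpart
  genome, and inter-anchor gaps are classified as deletion, insertion
  ("possible introgression" when the extra sequence has no homology in the
  query), inversion, or duplication.
* **synthetic_data** — a wheat-like allopolyploid simulator (diploids TU/AT,
  tetraploids WE/DW, hexaploid TA over A/B/D sub-genomes) that plants
  element copies with 9-bp TSDs on chosen lineage branches, plus large
  structural events, and emits an exact machine-readable truth table.

## The statistics at the core

For an insertion at locus *x* with flanks *L, R* the TSD is the longest
*t ∈ [2, 10]* with `suffix_t(L) = prefix_t(R)` (up to a mismatch budget).
A locus is called a **full site** in genome *G* when both 1000-bp flanks
place reciprocally-best in *G* (identity ≥ 0.90 over ≥ 0.80 of the flank)
and the inter-flank gap aligns to the family consensus at ≥ 0.80 identity
over ≥ 0.80 of the gap; an **empty site** when the flanks rejoin within
100 bp; a **rearranged candidate** when only one flank maps or the two
disagree. Venn regions count clusters of reciprocal full sites. Pairwise
distances use the TN93 closed form with empirical base frequencies and
pairwise deletion; trees are NJ with bootstrap percentages over resampled
columns.

## Worked example

```bash
mitedyn simulate --preset paper --seed 42 --outdir data/
mitedyn -v run --config run.yaml     # genomes + consensus from data/
```

with `run.yaml`:

```yaml
genomes: [data/TU.fasta, data/AT.fasta, data/WE.fasta, data/DW.fasta, data/TA.fasta]
consensus: data/consensus.fasta
outdir: out
seed: 42
```

The run prints per-stage counts and writes `out/summary.md`; at 500-kb
sub-genomes the Venn table reads:

```
| species subset | clusters |
| WE             | 15 |
| DW+TA+WE       | 10 |
| AT+TA          |  6 |
| DW             |  6 |
| TA             |  6 |
| DW+TA+TU+WE    |  2 |
| TU             |  2 |
| AT             |  1 |
```

i.e. the 48 planted clusters are recovered exactly: 15 insertions unique to
wild emmer, 10 shared by the three AB-carrying polyploids, 6 inherited from
the D-genome donor into bread wheat, the 2 ancient A-lineage insertions
shared by all four A-carrying species, and the per-species unique copies.
`out/tsd.tsv` lists each site's duplication (9-bp motifs for intact
junctions), `out/tree.nwk` the bootstrap-annotated NJ tree, and
`out/walk-reports/` one JSON per rearranged locus.

Individual stages are available as `mitedyn scan|tsd|compare|genes|phylo|walk`.

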