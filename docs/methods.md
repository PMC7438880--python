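# Methods

## Scope and model

`mitedyn` analyses the dynamics of a short (~300 bp) non-autonomous
transposable-element family across a set of related genomes: where its
copies are, what target site duplications they carry, which insertions are
shared between species, how the copies group phylogenetically, and what
large structural changes surround loci that are present in one genome but
not another. The package was shaped by the *Mariam* family of wheat — a
MITE-like family without terminal inverted repeats, with two sequence
variants (300 bp and 291 bp) that share their first 39 bp and last 50 bp —
but every module is parameterised and works on any FASTA assemblies plus
family consensus sequences.

Coordinates are 0-based half-open internally; every serialized table is
1-based inclusive with strand in its own column. Reversed printed bounds
(`start > end` meaning minus strand) are parsed on input, never emitted.
IUPAC ambiguity codes collapse to N, and N never counts as a match anywhere.

## Copy retrieval (te_search)

Copies are found by seed-and-extend: exact k-mers (k = 12) of the consensus
are located on both strands via a sorted-hash index, grouped by diagonal
(±15), and each group with at least 2 seeds defines a window that is
aligned by gapped local alignment (match +2, mismatch −3, gap open −5,
extend −2). Within a window the best alignment is masked and the alignment
repeated, so adjacent copies closer than one consensus length are still
reported separately; the unit tests confirm the scan is interval- and
score-identical to an exhaustive Smith–Waterman mask-and-repeat scan on
small genomes.

Hits are filtered by identity ≥ 0.80 over alignment columns (the 80/80
family-membership convention), consensus coverage ≥ 0.30 (so truncated
copies down to ~93/300 bp are reportable), and a raw score floor of 50.
An E-value threshold was deliberately not reproduced: E-values depend on
database size and search-tool internals, whereas explicit thresholds are
deterministic and testable. Overlapping hits (> 0.25 of the shorter) are
deduplicated keeping the higher score, ties broken by identity then
position — mirroring a best-hit-overhang style cleanup. Copies covering
≥ 0.85 of the consensus are classed `full`; the printed short class tops
out at 240/300 = 0.80, so 0.85 separates the classes cleanly. Copies in
the ambiguous 240–337 bp range are resolved by this coverage rule.

## TSD detection (tsd_flank)

Flanks are taken on the genome forward strand (junction-anchored), so
detection is independent of element orientation. The detector returns the
longest L ∈ [2, 10] whose left-flank suffix equals the right-flank prefix
within the mismatch budget (default 0; a study preset of 1 reflects the
"varying TSD" behaviour of older copies). One-base duplications are noise
(25% per junction) and are never reported. For copies with uncertain
boundaries an optional ±3 bp junction slide reports the best junction,
flagged `adjusted_junction`. Motif sets are summarised as a
position-frequency matrix over right-padded motifs; pad positions do not
contribute, so every column sums to 1 over its contributing motifs.

## Presence/absence and Venn regions (comparative)

Each locus is mapped into every other genome by its two 1000-bp flanks.
A flank placement must reach identity ≥ 0.90 over ≥ 0.80 of the flank and
survive a reciprocal-best check (the hit, aligned back to the source,
must land on the original locus). These thresholds are stricter than the
element-family rule because flanks are unique sequence; at the simulator's
divergences they cleanly separate orthologs (~2–4% diverged) from
homeologs (~10–14%).

Rules, in order: both flanks consistent and the gap carries the consensus
at ≥ 0.80/0.80 → `full_site`; both flanks with gap ≤ 100 bp (absorbing TSD
remnants and small indels) → `empty_site`; one flank only, or flanks on
different chromosomes/strands or > 50 kb apart → `rearranged_candidate`;
neither flank → `absent_locus`; otherwise `ambiguous`. Sites whose loci
reciprocally classify as full sites are clustered by connected components
(non-transitive triples therefore merge, with a warning). Venn regions
count full sites only — an empty site is "locus conserved, element absent"
and is reported separately in the matrix.

Gene association reports elements inside genes (CDS > exon > intron by
feature overlap) or within 500 bp up/downstream.

## Phylogenetics (phylo)

Maximum-likelihood tree search is out of scope; the package substitutes
TN93 distances + neighbor joining + column bootstrap, which is
deterministic, closed-form-testable, and reproduces the qualitative
cluster-membership statements the analysis needs (verified on planted
clades). The TN93 closed form uses empirical base frequencies over the
compared columns with pairwise deletion of gap/N columns (the common
default in desktop phylogenetics tools). Log-domain violations
(saturation, or fragment pairs with no shared columns) are flagged and
capped at 10% above the largest finite distance before tree building.
NJ clamps negative branch estimates to zero, moving the deficit to the
sister branch. Bootstrap support is the percentage of replicate trees
containing each internal bipartition; branches below the cutoff (45 in the
study presets) or of zero length collapse into polytomies. All stochastic
steps take explicit seeds (default 42) and are bit-reproducible.

The progressive aligner builds a guide order by neighbor joining on a
shared-k-mer distance (k = 6) and merges profiles by global affine-gap
alignment on expected column scores; the two-sequence case equals the
exact DP optimum, which the tests assert. Subfamily assignment aligns each
copy to every consensus with free end gaps on the consensus side only —
a truncated copy is judged over the region it covers, but a chimera must
pay for its non-matching half — and assigns the best family if its
identity is ≥ 0.80 and beats the runner-up by ≥ 0.03; anything inside that
band is `unassigned` (candidate intermediate).

## Rearrangement typing (rearrangement)

The dot-plot step of the original analysis is manual; its formalisation
here is the package's main engineering contribution. Anchors are maximal
same-diagonal runs of exact 12-mers, end-extended and filtered by length
and ungapped identity (1000 bp / 0.90 at paper scale; a `desk` preset uses
300 bp anchors with 500-bp minimum events for hundred-kb test genomes).
Events are reported target-relative-to-query, with both spans listed:
query gap with target continuity → deletion; target gap with query
continuity → insertion, annotated "possible introgression" when the gap
sequence has no anchor anywhere in the query; a run of reverse-orientation
anchors flanked by forward chains → inversion; one query span matched by
two near-disjoint target spans → duplication (the longest placement stays
on the chain; more than two copies are noted `multi-copy` without
pairing). An insertion gap explained by a duplication copy is suppressed
so each planted event yields exactly one call. Assigning events to
evolutionary lineages (e.g. "following tetraploidization") is
interpretation and is left to the user.

Chromosome walking grows the query window from 5 kb per side by 10-kb
steps (to 100 kb) until anchors cover both query ends on one target
chromosome; the same-named chromosome is tried first, then all
chromosomes, and a placement found only by that fallback is noted as
translocated context. Unplaced loci return an `unresolved` report rather
than an error.

## The simulator (synthetic_data)

The generator models the allopolyploid history of wheat: one root
sequence (500 kb per sub-genome, GC 0.46) diverges into A/B/D sub-genome
ancestors at 5% substitutions each, deeper than the 2% applied on each
within-lineage split (root→TU, root→AB, AB→WE/DW/TA, D→AT/TA), so
homeolog confusion in flank mapping is measurable but the true ortholog
always wins. The background process is substitution-only — no indels — so
every planted coordinate stays exact; indels enter only through planted
elements and structural events. Elements are planted on a chosen lineage
branch (hence inherited by all descendants), each with a 9-bp duplication
of the host target site, 1% copy-specific mutations, random strand, and
positions drawn once in root coordinates with ≥ 3 kb spacing and 6 kb end
margins so flank windows never collide. Truncated copies keep one intact
consensus end and span 110–240 bp: the printed short class reaches ~93 bp,
but at the default 0.30 coverage floor a 93-bp copy sits exactly on the
detection threshold, where end-trimming of one or two mutated terminal
bases would make planted-truth recovery non-deterministic; a dedicated
test still plants an unmutated 93-bp fragment and shows it is caught.

The five-genome preset plants the published sharing structure — 2 ancient
insertions on the A lineage (TU+WE+DW+TA, following the Venn-diagram
caption's four-species reading, which is the only one realisable when no
sub-genome is common to all five species), 6 on the D lineage (AT+TA), 10
on the AB lineage (WE+DW+TA), 15/6/6/1/2 species-unique — with a generated
consensus pair (300 bp and 291 bp sharing a 39-bp head and 50-bp tail;
the published consensus sequences are not printed in the text, and an
optional loader accepts the real pair when the user has it).

What the simulator does not model: real TE landscapes (nested LTR
retrotransposons, CACTA background), recombination, within-species
polymorphism, assembly gaps, and background indels. Passing the
planted-truth suites therefore demonstrates the correctness of the
machinery under clean polyploid divergence, not performance on
multi-gigabase drafts; headline copy tallies from the real genomes
(60 + 34 insertions etc.) are not reproducible at this scale by design.

## Problem sizes and numerical choices

Desk-scale defaults keep the full test suite and the end-to-end
reproduction scripts within minutes on one CPU: 500-kb sub-genomes for the
five-genome scenario, ≤ 50-kb genomes for oracle-equivalence suites,
20 replicates per cell of the event-recovery grid (four types ×
1/2/5/10 kb, desk anchor preset), 100 bootstrap replicates. Ties break
deterministically everywhere (first-in-scan-order joins, alphabetical
consensus symbols, leftmost dedup), and every random draw flows from an
explicit seed, so reruns are byte-identical.
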