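# Methods

This document describes the models, algorithms, parameter defaults and
numerical conventions used by `mitorecomb`, and the rationale for each
choice.

## Coordinate model

Genomes are circular. All API coordinates are 0-based half-open
`CircularInterval(start, end, genome_length)` values:

- `start < end` is an ordinary arc; `end == genome_length` is a plain
  suffix (no wrap).
- `start >= end` with `end != genome_length` wraps through the origin.
- `start == end` denotes the full circle (span = genome length).
- `span = (end - start) mod genome_length`, except the full-circle case.

TSV and GFF3 outputs use 1-based inclusive coordinates; features that
wrap the origin are written as two-segment GFF3 joins (suffix segment
first) and round-trip losslessly, as do GenBank origin-spanning compound
locations.

## Repeat finding

`find_repeat_pairs` discovers dispersed repeat pairs by seed-and-extend:

1. **Seeding.** All exact 20-mers of the genome are indexed. Direct
   candidate pairs are seed matches between the sequence and itself
   (performed on the doubled sequence so origin-spanning copies are
   found); inverted candidates are matches between the sequence and its
   reverse complement. Because a repeat copy aligned to the reverse
   complement of its partner is *collinear*, both cases share one
   diagonal invariant: seeds of the same pair have constant
   `(j - i) mod L` (direct) or `(p - i) mod L` (inverted, `p` in
   reverse-complement coordinates).
2. **Chaining.** Seeds on the same diagonal within a 15 bp band are
   chained when consecutive seeds are at most 60 bp apart.
3. **Extension and alignment.** Each chain defines two windows, padded by
   a 60 bp margin, which are aligned with Biopython's affine-gap local
   aligner: match +1, mismatch −2, gap open −7, gap extend −2 (a gap of
   length *g* costs 5 + 2*g*). Mismatch and gap penalties are steep so an
   alignment at the 85 % identity floor still has positive score and
   extensions stop quickly in random sequence. Among co-optimal
   alignments the one with the most matches, then fewest columns, then
   smallest start coordinates is kept, making results deterministic.
4. **Qualification and deduplication.** A pair qualifies with ≥50 aligned
   columns and ≥85 % identity (matches / columns). Mirror duplicates are
   removed (copy1 is always the copy with the smaller start) and pairs
   wholly contained in a higher-scoring pair are collapsed.

**Sensitivity limit.** Seeding requires at least one exact 20-mer shared
between the copies. Repeat pairs whose substitutions are denser than one
per 20 bp everywhere carry no exact 20-mer and are undetectable by this
method; this is an inherent property of seeded search, shared by standard
aligners with comparable word sizes. The validation suite therefore
compares against an exhaustive dynamic-programming oracle on genomes
whose planted substitutions are ≥30 bp apart, inside the documented
sensitivity envelope.

`select_assayable_repeats` keeps pairs of 50–250 bp (inclusive) with
non-overlapping copies. The lower bound matches the finder floor; the
upper bound is the longest repeat a ~350 bp paired-end insert can span
while still reaching ≥50 bp into both flanks, so that conformation-
informative read pairs exist.

## Reference panels

For each repeat pair `build_reference_panel` assembles junction
references of repeat ±200 bp flanks, truncating a flank where it would
run into the partner copy (flagged `truncated`). For inverted pairs,
copy2 and its flanks are reverse-complemented so every member reads on
one strand.

- **Identical copies (100 % identity):** the repeat interior cannot
  distinguish which copy a read came from, so only the flank combinations
  matter — 4 members: the two originals and the two exchanged-flank
  (recombinant) junctions.
- **Diverged copies (<100 % identity):** the interior variant is
  informative, giving 8 members — 2 originals, 4 crossover products
  (each flank pairing with each interior), and 2 conversion-style
  members (original flanks around the other copy's interior).

## Read-pair classification

`classify_read_pairs` aligns each mate to each panel member with edlib
(infix / "HW" mode, both orientations) and accepts a (pair, member)
placement when:

- each mate aligns at ≥98 % identity (computed from the extended CIGAR
  over alignment columns);
- the mates face inward on the member with implied insert ≤1000 bp;
- the union footprint of the two mates covers ≥50 bp of *both* flanks —
  the requirement that makes a pair conformation-informative.

The placement with the lowest total edit distance wins; when master and
recombinant conformations tie exactly, the pair is counted *ambiguous*.
Counts are conserved: master + alternative + ambiguous + unmatched equals
the number of input pairs.

A k-mer prescreen makes this fast: the panel's 20-mer set (all positions,
plus reverse complements) is probed with mate 20-mers at stride 10. This
is lossless at the identity threshold — a 150 bp mate at ≥98 % identity
has ≤3 edits, which always leaves an exact run of ≥29 bp, and any 29 bp
run contains 10 consecutive 20-mer starts, at least one of which is on
the stride grid.

## Recombination rate and cohort statistics

The per-repeat rate is
`100 · alternative / (master + alternative)` per cent, computed in
decimal arithmetic and rounded to 2 decimals, **half-up** (so 11.455 →
11.46, matching conventional hand-rounding of published percentages; the
common round-half-even would give 11.45 and spurious mismatches).
Ambiguous and unmatched pairs are excluded from the denominator. A repeat
with zero informative pairs raises `UndefinedRateError` rather than
reporting a fabricated 0 %.

`summarize_events` computes cohort statistics over events: median /
min / max rate (even-cohort median = midpoint of the central pair, in
decimal arithmetic), mean repeat length (rounded half-up to integer),
counts and percentage of repeats >100 bp, the median rate of small
(<100 bp) repeats, and 2×2 direction-by-outcome tables for gene-order
change and genes affected.

### Packaged event fixture

The package ships a checksummed TSV of 26 curated recombination events
across 16 liverwort species (`data/curated_events.tsv`). Percentages are
stored exactly as printed in the source material — with their original,
unequal precision — and the loader recomputes each rate from the read
counts and cross-checks it against the stored percentage *at its stored
precision*, so the fixture cannot silently drift from the counts. One row
whose master/alternative percentages do not sum to 100 (a rounding
artifact in the source) is flagged `percent_discrepancy` rather than
"corrected". Any edit to the fixture breaks the SHA-256 check and strict
loading fails.

## Structure analysis

Gene orders are signed circular permutations extracted from annotations
(sign = strand; duplicate gene names get positional suffixes). Two orders
are equal when one is a rotation or a reflection (reverse + sign flip) of
the other; `canonical_form` picks the lexicographic minimum over all
rotations of both readings.

**"Gene order changed"** is operationalized as a change of the circular
signed *adjacency set*, pooled over all product molecules, relative to
the master circle. This is the only annotation-level definition that is
both computable and explains the empirical direct/inverted asymmetry:
a direct-repeat excision whose inter-copy segment contains no genes
produces a gene-free subcircle and leaves every gene adjacency intact
(unchanged), whereas an inversion with genes inside the segment always
rewires adjacencies (changed).

`apply_recombination`:

- **inverted pair** → one product with the inter-copy block reversed and
  sign-flipped (an involution: applying the same inversion again restores
  the master order);
- **direct pair** → two products, the main circle and the excised
  subcircle; the gene multiset is conserved across products.

**Genes affected** are genes overlapping a repeat *copy* (not the
inter-copy segment); genes fully contained in a copy are additionally
flagged high-impact.

`rearrangement_distance` offers two metrics, labelled in all outputs:
*breakpoint* (number of adjacencies of one order absent from the other,
over their shared genes)
and *inversion* (minimum number of block inversions, computed exactly by
bidirectional breadth-first search over canonical forms; practical for
gene orders up to ~12 genes, which covers the structural gene sets used
here).

## Composition profiling

`partition_genome` tiles the circle into exon, intron and spacer base
pairs that always sum to the genome length: intron children take their
annotated extent, exonic bases are the remaining gene bases (genes
without substructure are wholly exonic), everything else is spacer, with
overlaps resolved in that precedence order.

Spacer ORFs are ATG→stop open reading frames (≥100 codons, stop
included) on
both strands in all six frames, allowed to wrap the origin. SSRs use
motif-length-dependent minimum copy numbers {1: 10, 2: 6, 3: 5, 4: 5,
5: 5, 6: 5} and are reported at their primitive period (an `ATAT` run is
an `AT` run).

Introns are named `<host>i<pos><group>` where `pos` is the insertion
position in the host's coding sequence read 5′→3′ (on the minus strand,
`coding_length − plus_strand_offset`), matched against a packaged
insertion-site catalog to assign group I/II identity; unmatched introns
are reported as novel. The cross-species inventory matrix ends with a
per-species total row.

## Simulation

`generate_genome` deterministically builds an annotated circular genome:
random intergenic sequence at a configurable GC fraction, non-overlapping
genes with stop-free CDSs, introns inserted at catalog positions for
catalog genes, and planted repeat pairs at the requested length,
direction and identity (divergence = uniformly placed substitutions).
Identical config + seed gives byte-identical output.

`simulate_read_pairs` draws inward-facing 2×150 bp pairs from a molecule
mixture: the master circle plus, per planted repeat, its recombinant
product(s) at the requested alternative fraction *f*. Insert sizes are
normal (mean 350, sd 35), clipped to [2·read_length, mean + 4·sd];
sequencing errors are i.i.d. substitutions. The number of pairs is
`floor(coverage · L / (2 · read_length))`.

This mixture makes the detector's estimator unbiased by construction:
junction-spanning reads arise from the master circle in proportion to
`(1 − f)` and from the alternative conformation in proportion to `f`, so
the expected alternative fraction of informative pairs equals `f`. The
validation suite verifies recovery within 3 binomial standard errors
across `f ∈ {0.02, 0.1, 0.3}` and exact zero alternative support at
`f = 0` on error-free reads.

Default validation problem sizes (50 kb genomes, 300× coverage, 150 bp
repeats) are chosen so one full simulate-sequence-detect replicate runs
in ~1–2 s on a single core, keeping the complete suite fast while the
genomes remain large enough for realistic flank context.

## Determinism and provenance

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; there is no global-state seeding. Pipeline
outputs carry a provenance header (`# mitorecomb <version>
config=<hash> seed=<seed>`) where the config hash covers every parameter
that affects results (output paths and logging are excluded). Reruns with
an unchanged hash reuse cached detection outputs and are byte-identical.

## Limitations

- The repeat finder cannot detect pairs without a shared exact 20-mer
  (see the sensitivity limit above), and reports dispersed pairs only —
  tandem arrays and nested repeat structures are out of scope.
- Recombination assay power is bounded by the insert size: repeats longer
  than ~250 bp cannot be spanned by short-read pairs and are excluded
  from `select_assayable_repeats`.
- The exact inversion distance is exponential in gene count and is
  intended for small structural gene sets (≤ ~12 genes); the breakpoint
  metric has no such limit.
- The read simulator models substitution errors only (no indels) and a
  single insert-size distribution.
- `apply_recombination` models one recombination event at a time;
  iterated or interacting events are not composed.
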