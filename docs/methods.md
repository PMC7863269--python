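# Methods

## The analysis model

A plastome is treated as a circular string over {A,C,G,T,N} carrying gene
features (protein-coding, tRNA, rRNA; multi-part features encode introns).
The quadripartite layout is *defined* here by the longest exact inverted
repeat: k-mer seeds (default k = 25) between the doubled sequence and its
reverse complement are grouped by the anti-diagonal invariant a+b+m and
extended ungapped; the maximal pair partitions the circle into four arcs,
the longer single-copy arc is the LSC, and the record is rotated so the
genome reads LSC, IRb, SSC, IRa from position 0.  Exact matching is a
deliberate choice: plastome IRs are long (tens of kb) and homogenized by
concerted evolution, and exactness buys byte-testable invariants —
revcomp(IRb) == IRa, region lengths summing to the genome, and
rotation/orientation invariance of the partition.  Deposited records whose
two IR copies differ by a few bases near the boundaries would need a
mismatch-tolerant fallback; the detector reports failure (or ambiguity,
listing candidates) rather than guessing.  `min_ir` defaults to 10 kb,
far above any chance inverted repeat and far below a real IR.

SSRs are maximal perfect tandem repeats of primitive 1–6 bp motifs with
inclusive minimum repeat counts {1:10, 2:5, 3:4, 4:3, 5:3, 6:3}, the
GMATA-style thresholds customary for plastome scans (configurable if a
strict ">" reading is wanted).  Runs are reported at their leftmost phase
and truncated to whole units; primitivity makes "ATATAT…" a dinucleotide
locus and nothing else; a locus contained in a longer reported locus is
suppressed; N breaks runs.  Motifs are reported as read on the forward
strand, with a canonicalized (rotation+strand minimal) view available for
pooled motif tables.  Both IR copies of a duplicated locus are counted by
default; a de-duplicating switch drops the IRa copy.

Indels are extracted from a whole-genome alignment against a designated
reference row.  A maximal run of gap-bearing columns whose per-taxon gap
pattern is constant is one event; taxa sharing the identical span are
co-carriers, overlapping-but-unequal spans split into separate events (the
most conservative reproducible merging rule).  Events are left-normalized
on the ungapped reference — deletions slide left while the flanking base
equals the last deleted base; insertions rotate their sequence — so aligner
placement ambiguity in repeats cannot smear positions.  Polarity is
reported against the reference only; no ancestral-state inference.
Slippage classification ties directly to the SSR definition: an event is
SSR-related iff its sequence is whole copies of some unit u (|u| ≤ 6) and
the allele with more copies, together with its flanks, forms a perfect
in-phase tandem run meeting the SSR threshold for |u|.  Simple indel coding
turns each event into one binary fragment-presence character; constant
characters are dropped before tree building.

Diversity statistics follow the complete-deletion convention (a column
counts only if every row has an unambiguous base; ambiguity codes other
than N are mapped to N on load): π is the mean pairwise difference per
valid column; a column is variable with ≥ 2 states and parsimony-
informative with ≥ 2 states each in ≥ 2 rows.  Printed percentages use the
full aligned length as denominator, matching how comparative tables are
usually quoted — so `pct_variable` and π use different denominators by
design.  Sliding windows (600 bp window, 100 bp step by default) advance
over alignment columns with complete deletion inside each window; a window
with no valid column carries an undefined-π flag rather than 0.  Trailing
partial windows are dropped by default (emitted, flagged, only if at least
half a window remains and `include_partial` is set).  Markers are extracted
by anchor genes through the reference row: one anchor means the gene body,
several mean the span from the end of the first to the start of the last
(strand-agnostic), which covers both plain spacers (psbM–trnD) and
composite regions (rpl22–rps19–rpl2).

Trees: p-distance uses pairwise deletion; indel distance is normalized
Hamming on the binary coding.  Neighbor joining is implemented with an
explicit tie-break (lexicographically smallest pair of leaf-label sets at
equal Q, compared after rounding Q to 12 decimals) so output is invariant
to input row order; negative branch lengths are clamped to zero with a
warning.  Bootstrap support resamples columns with replacement and scores
each internal bipartition of the full-data tree by its replicate frequency.
ML and Bayesian inference are intentionally out of scope; the package
writes relaxed PHYLIP and NEXUS for the external programs.

## The synthetic-data generator

The generator emulates a six-species congeneric plastome comparison at the
regime where these rules operate, and doubles as the ground-truth oracle
for every stage.  Defaults: LSC 84 kb, IR 25 kb, SSC 18.7 kb; a 113-gene
catalog (79 protein-coding, 30 tRNA, 4 rRNA; 17 genes mirrored into IRa)
with plausible gene order, lengths, and intron placement, and fixed widths
for the classic marker spacers; per-region GC (LSC 0.358, IR 0.432,
SSC 0.315).  A fixed six-taxon guide tree carries branch lengths (expected
substitutions/site) whose mean pairwise path is ≈ 1e-3; regional rate
multipliers (LSC 1.3, IR 0.3, SSC 1.8) reproduce the cold-IR/hot-SSC
pattern, and four marker hotspots (rpl22–rps19–rpl2 ×6.5; psbM–trnD,
trnR–trnT, trnT–trnL ×5) create localized peaks an order of magnitude
above background.  Substitutions use per-site Bernoulli draws with a 2:1
transition:transversion weight; IR mutations are applied to IRb and
mirrored into IRa (concerted evolution).

SSR tracts are planted in the ancestor (34 single-copy + 1 IR tract by
default, 99 % of mononucleotides A/T, unit counts at threshold plus a
geometric tail); background sequence contributes a further handful of
chance loci per genome, bringing per-genome totals to the low-to-mid 40s.
Slippage changes a tract by ±1 unit (expansion:contraction 55:45) at
350 events per tract per unit branch length; non-SSR indels occur at
0.32 events per single-copy site per unit branch length with a mixed size
law (geometric mode 1 bp, a mid-size tail, and 2 % large 500–1000 bp
deletions), yielding ~90–120 events per run at ~20–25 % SSR-related.
Events are placed with footprint padding so they never overlap or touch
(which keeps gap runs unambiguous), never cross a region boundary, avoid
exons with probability 0.9, and never swallow a whole gene (congeneric
plastomes conserve the gene complement).  Evolution happens directly on an
explicit alignment representation — insertions add columns, deletions gap
their carriers — so the true alignment requires no external aligner and
round-trips exactly.

What the generator does *not* emulate, hence what passing tests do not
show about real data: IR boundary expansion/contraction (IR length is
invariant and its copies byte-identical; four junction bases are pinned so
the maximal exact IR equals the simulated one), indels inside the IR,
substitutions within inserted fragments after their creation, codon
structure and selection, rearrangements, sequencing/assembly error, and
aligner artifacts — real MAFFT output may place gaps differently than the
truth alignment, which is precisely why calls are left-normalized.
rps12 trans-splicing and the matK-inside-trnK nesting are simplified to
independent gene features.

## Numerical and interface choices

Coordinates are 0-based half-open everywhere internally; only rendered
tables print 1-based positions.  Alignments are uint8 matrices; window π
uses cumulative sums of per-column pairwise-difference counts, so a
153 kb × 6 scan is vectorized end to end.  All randomness in the pipeline
(bootstrap) and generator flows from one integer seed through
`numpy.random.default_rng`; the pipeline writes a sha256 manifest and
reruns are byte-identical (the GenBank writer pins the record date).
Stages are always recomputed rather than cache-skipped — they are cheap
and deterministic, and the manifest makes reuse verifiable rather than
assumed.  Degenerate inputs raise typed errors instead of returning
sentinel values: no IR ≥ min_ir, ambiguous equal-length IR pairs, π over
zero valid columns, all-gap alignment columns, constant indel matrices,
and taxon pairs with no comparable sites.

Problem sizes used by the test suite and the acceptance script were chosen
to keep the whole loop interactive: one study-scale (~153 kb × 6) run for
the headline statistics and recovery rates, 8 kb-genome replicates (50 for
the hotspot co-location check, 30 in the acceptance script), 200 random
2 kb sequences for the SSR oracle sweep, and 40 small replicates for the
substitution-expectation check.  A brute-force oracle accompanies each
operation in the tests (naive tandem-run enumeration, per-column recounts,
graph-path additive distances), sharing no code with the implementation.

## Known limitations

Exact-IR detection will reject plastomes whose IR copies differ; the SSR
scanner handles perfect repeats only (no compound/interrupted models); the
indel caller assumes a trustworthy alignment and one reference taxon; the
slippage classifier tests in-phase runs only, so out-of-phase repeat
context is called non-SSR; NJ is a desk-scale stand-in whose topology —
not branch-length — claims should be compared with ML/BI runs from the
exported files.  Reproducing the published per-accession numbers requires
downloading the deposited genomes and an external alignment run; the
repository carries the test harness for that comparison but not the data.
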