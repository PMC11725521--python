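# Methods

## Read classification and the k-mer filter

The workflow assumes an upstream read classifier that labels HiFi reads
as plastid, mitochondrial or nuclear. Such classifiers systematically
mislabel reads covering nuclear insertions of organellar DNA (NUPTs and
NUMTs) and reads from high-copy nuclear repeats; the k-mer filter removes
both using only coverage statistics.

Counting is canonical: each 31-mer window is keyed by the lexicographic
minimum of the word and its reverse complement (A<C<G<T maps to a 2-bit
code, so integer comparison equals lexicographic comparison); windows
containing N are skipped. Count tables are built **per class** — one from
plastid-labeled reads, and one from mitochondrion-labeled reads after
chloroplast-read removal — so the mitochondrial cohort median reflects
the mitochondrial, not chloroplast, coverage. Each read's median k-mer
count (*rmkc*; even-length medians are the mean of the two middle values)
represents the read; the class median *mkc* of the *rmkc* values sets
*lkc* = 0.3 × *mkc* and *hkc* = 5 × *mkc*. A read is removed when
strictly more than one-fifth of its k-mer counts are strictly below *lkc*
or strictly above *hkc*; a read shorter than k is removed as unassessable.
No minimum window count is imposed on short reads: the fraction is taken
over whatever windows exist.

The filter's power comes from the coverage asymmetry of whole-plant DNA:
organellar genomes sit at tens-to-hundreds-fold the nuclear coverage, so
nuclear and chimeric reads carry k-mers far below *lkc*. Its failure
modes are the same asymmetry's edges: an organelle read sampled across a
coverage trough, or genuinely shared organelle/nuclear k-mers in very
recent insertions.

## Chloroplast topology and isomers

Links are canonicalized (each replaced by the lexicographically smaller
of itself and its orientation-flipped complement; duplicates collapsed).
Short (< 50 bp, configurable) isolated segments are pruned as assembler
debris, and self-loops on the candidate IR are dropped with a warning. A
graph is **quadripartite** when it has exactly 3 segments and 4 canonical
links, one segment incident to all four links (the IR) and the other two
incident to two each, and the alternating circuit
single-copy → IR → single-copy → rc(IR) exists; the circuit is found by
brute force over the 16 orientation/order combinations. The longer
single-copy segment is the LSC, ties broken by lexicographic id.
**Circular** requires a single segment whose only link joins its end to
its start. Any dangling segment end makes the call **incomplete**;
everything else is **other**. Retry policy on incomplete graphs lives in
the pipeline, not here.

Isomer A is the walk LSC·IR·SSC·rc(IR) with each link's exact-match
overlap trimmed from the successor segment; isomer B reverse-complements
the SSC contribution in place. The circular output starts at the LSC
start (or the stored origin for single circles); no minimal-rotation
normalization is applied, for determinism and speed. A graph whose IR is
shorter than the read length usually collapses to a single circle and is
classified by whatever structure it shows.

## Mitochondrial refinement and completeness

Mitochondrion-labeled reads are aligned to the chloroplast assembly
*graph* (aligning to a linearized circle would clip alignments at the
origin and at heteroplasmy junctions). A read is removed when **any** of
its alignments has query clips ≤ 100 bp on both sides (inclusive) and
identity (GAF matches/blocklen) strictly above 0.95. Unaligned reads are
kept.

Completeness of the mitochondrial assembly is presence/absence of a
41-gene panel of conserved mitochondrial protein-coding genes (ATP
synthase, cytochrome c maturation, respiratory complexes, maturase,
mttB, ribosomal proteins, succinate dehydrogenase). A gene is present
when any hit reaches e-value ≤ 1e-3 (inclusive, matching aligner-side
-evalue semantics). Panel membership is configuration; the size of 41 is
asserted. Copy number and orientation are ignored because assembly
graphs collapse long repeats.

## NUPT/NUMT identification

HSPs from organelle-vs-nuclear BLAST (outfmt 6) are normalized to
0-based half-open nuclear intervals (minus-strand hits flagged and
flipped). Retention requires identity > 80% and length > 100 bp, both
strict. An HSP completely embedded (shared endpoints allowed) in a
strictly longer HSP on the same nuclear sequence is removed; exact
duplicates keep the highest bitscore, then input order. Remaining
intervals merge transitively at distance 0 (book-ended intervals merge,
matching the interval tool's default); the merged identity is the
**unweighted** mean of member HSP identities (a length-weighted option
exists but is off by default).

## Substitution spectra and cytosine context

Substitutions are extracted directly from `cs` difference strings of
nuclear-copy-vs-organelle alignments; indels and multi-base blocks are
ignored. Each substitution is collapsed onto the six strand-symmetric
classes (purine-reference records complemented). Context is assigned on
the **organellar** sequence — the pre-insertion ancestral state — with
the pyrimidine-strand C at position i: CG if base i+1 is G; CHG if i+1 is
H (A/C/T) and i+2 is G; CHH if both are H; G-reference sites are resolved
on the reverse complement; positions within 2 bases of a sequence end are
NA. Per-context site counts over the aligned organellar intervals provide
denominators so context-specific rates, not just counts, can be compared.

## siRNA enrichment test

Observed overlap is the total intersection in bases between features
(siRNA loci) and annotations (merged insertions). The null re-places each
feature uniformly within its own chromosome, length preserved, features
free to overlap each other, 1,000 samples by default under a fixed seed.
This randomizes the features and keeps the annotations fixed — a
simplification of workspace-based tools, stated openly. The empirical
p-value is (1 + #{null ≥ observed}) / (1 + n); its minimum at 1,000
samples is 1/1001. The 95% CI is on the observed fold,
observed/null₉₇.₅ to observed/null₂.₅, which under the null covers
fold = 1 at the nominal rate (measured 95–97% over 200 replicate seeds in
the test suite); when the null's 2.5th percentile is zero the upper bound
is reported as infinite. Cross-species summaries report Pearson
correlations of cumulative insertion length against nuclear genome size
on both raw and log10 scales, since the appropriate scale is a judgment
call; fewer than 3 species yields NaN.

## Synthetic fixtures: what they emulate and what they do not

Generators are seeded (`numpy.random.default_rng`) and bit-reproducible.
The default fixture uses a 23 kb chloroplast (12 kb LSC, 3 kb IR, 5 kb
SSC), a 30 kb mitochondrial circle plus a 5 kb small circle, and a
120 kb nuclear background with 8 planted NUPTs at identities 92–99% —
sizes chosen so the full pipeline runs in seconds on one CPU while
preserving the structural features the methods depend on (quadripartite
graph, origin-spanning reads, coverage asymmetry). Coverage defaults are
chloroplast 50×, mitochondrion 20×, nuclear 1×. Reads have lognormal
lengths (mean 2 kb, SD 300 bp — scaled down from real HiFi in proportion
to the genomes) and substitution-only errors at 0.1%; homopolymer indels,
chimeric reads and quality-score structure are not modeled, so passing
tests demonstrate the algorithms' correctness under the stated model, not
robustness to every real-data artifact. Planted insertions draw
substitution classes from a programmable distribution (default 60%
C:G>T:A, concentrated 60/30/10 at CG/CHG/CHH sites, emulating
deamination of methylated cytosines); the planted count is
round((1 − identity) × length), so recovery can be checked exactly.

The oracle assembler emits the truth graph when the supplied read pool is
≥ 90% on-target and covers the target at ≥ 20× (chloroplast) or ≥ 10×
(mitochondrion, whose genuine coverage is lower), and otherwise a broken
graph with dangling ends — a contract, not a simulation of assembler
behavior. The oracle graph aligner gives chloroplast-origin reads
end-to-end alignments at 99.9% identity and others none.

## Pipeline

Chloroplast first: the assembly loop samples 800 reads per round
(roughly 100× for a real chloroplast) without replacement, each round
seeded with config.seed + round, up to max_rounds = 10 (the cap is this
package's choice; it is configurable). If the pool is smaller than one
round's sample, all reads are used once. Reads labeled nuclear or unknown
are discarded at the branch point. The mitochondrial branch runs
refinement against the finished chloroplast graph, then a fresh per-class
k-mer filter (a fresh count table, so *mkc* reflects the refined pool),
then a single assembler run on all remaining reads. Exit status 0 means a
complete (quadripartite or circular) chloroplast; 1 means the loop
exhausted its rounds. Read counts are conserved at every stage
(in = kept + removed, asserted).

External tools are adapter contracts: in-process callables for the
oracles, or subprocess command templates (`{reads}`, `{graph}`, `{out}`
placeholders) for real classifier/assembler/aligner binaries. Tests use
the in-process oracles exclusively.

## Numerical and design notes

- All internal coordinates are 0-based half-open; 1-based inclusive only
  at the BLAST-6 boundary.
- Bases are upcased on input; non-ACGTN characters map to N. GFA overlaps
  other than `*`/`<n>M` are rejected rather than silently trimmed.
- Threshold comparisons mirror their definitions exactly: filter outlier
  fraction strictly greater than 1/5; counts strictly below/above
  lkc/hkc; contig labeling coverage > 0.90 and similarity > 0.95 strict;
  clip bounds inclusive, identity strict; HSP bounds strict; completeness
  e-value inclusive.
- The k-mer filter assesses reads with as few as one valid window;
  degenerate inputs (empty graphs, empty read sets, features longer than
  their chromosome) raise structured errors rather than propagating NaN.

## Known limitations

Disk-backed k-mer counting is out of scope (tables are in-memory dicts,
fine to ~10× genome-scale fixtures, not 50-Gb HiFi archives). Graphs with
more than three chloroplast segments are classified "other", not
untangled. The enrichment null does not model workspace masking or
feature–feature exclusion. The substitution caller handles single-base
mismatches only, by design.
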