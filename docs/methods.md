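# Methods

This note documents the models, parameter choices and numerical conventions
behind `igtscan`, and what its synthetic benchmarks do and do not establish
about real genome data.

## Coordinates and sequence alphabet

Internal coordinates are 0-based half-open everywhere.  On-disk tables are
1-based inclusive (the convention of gene annotation tables), except BED,
which keeps its native 0-based half-open form.  Sequences are normalised to
uppercase {A, C, G, T, N}: U→T, anything else →N with a per-record count.
N is never a match: it mismatches every symbol (including N) in both scoring
and identity, and seed words containing N are skipped.

## Local alignment engine

The transfer screens historically run on BLASTN with three gates: E-value
≤ 1e−5, ≥ 95% identity, and a minimum hit length (100 bp for nuclear
insertions, 50 bp for organelle-to-organelle ones).  BLAST publications
rarely pin down scoring, so the engine fixes a documented scheme chosen to
mirror blastn-like defaults:

* match +1, mismatch −2; a gap of length *k* costs 5 + 2*k* (open −5,
  extend −2 in the BLAST convention, i.e. first gap column −7, later −2);
* ungapped Karlin–Altschul statistics with K = 0.71, λ = 1.37, giving
  deterministic E = K·m·n·exp(−λS) for query length m and target length n.

The search is classic seed-and-extend: exact `word_size` (default 11) seeds
on both strands, seeds grouped into diagonal-band clusters (band ±10 bp,
query join gap ≤ 150 bp), an ungapped X-drop extension (X = 25) as a cheap
pre-filter, and then an **exact** affine-gap Smith–Waterman restricted to a
window around the cluster.  Because the window DP is exact, the best reported
score provably equals the global Smith–Waterman optimum whenever (i) the
optimal alignment contains at least one exact seed word and (ii) it fits the
window; windows are padded (whole-query for queries ≤ 512 bp, 120 bp
otherwise) so that planted-scale events satisfy (ii).  The in-row gap
recurrence is vectorised with a prefix-max scan, which is exact for affine
costs; the traceback reconstructs matches and aligned columns by value
matching, which always follows some optimal path.

The pre-filter skip rule is derived from the gates themselves: a reportable
HSP of length ≥ L and identity ≥ p has score ≥ L(8p − 7) (each non-match
column costs at most 7 including a worst-case gap open), and the E-value
gate implies S ≥ ln(K·m·n / E_max)/λ.  A cluster whose best ungapped
extension is more than 15 below that bound cannot produce a reportable hit
and is dropped — this keeps random 11-mer seed noise cheap without ever
discarding a qualifying alignment.

"Exact match (95%)" is read as alignment identity over the HSP, the standard
BLAST-filter reading; a `query_coverage` mode is exposed as the alternative
interpretation.  Low-complexity masking is off by default; a flag enables a
dust-like seed filter (words built from ≤ 2 distinct bases never seed).
Overlapping HSPs on the same strand within one diagonal band are merged
keeping the highest raw score, preventing double counting of transferred bp
while leaving cross-diagonal overlaps (distinct insertion events) separate.
Ties in best-HSP selection break by (lower E-value, longer alignment, lower
target start).

For genome self-comparison the trivial identity diagonal is excluded at
seeding time and additionally forbidden cell-wise inside window DPs, so
near-diagonal windows cannot collapse onto the self-match.

## Gene fate

A gene's state for a species is decided by presence/absence of gated hits in
the donor organelle and the recipient genome, with "full length"
operationalised as chained query coverage ≥ 95% (configurable).  Recipient
hits are chained by dynamic programming over hits sorted by query start:
chainable hits share target record and strand, respect query and target
order (≤ 10 bp overlap tolerance), and may be separated by recipient-side
gaps of any size — transferred genes are often split by later insertions.
Coverage counts the chained query union.  Pseudogene calls are
truncation-based; internal stop codons are deliberately not assessed (that
evidence belongs to expression-level analyses outside this package's scope).
Genes shorter than the length gate are classified with the gate lowered to
the gene length and flagged.  Raising the full-length cutoff can only move
calls from intact to pseudogene, never the reverse.

The default 24-gene reference set uses standard plant mitochondrial gene
names (nad/cox/atp/ccm/rps/rpl families) with synthetic per-seed sequences
of 300–1500 bp; it is a documented stand-in, replaceable by any
(GeneModel, sequence) list.

## Junction micro-homology

A micro-homology is the longest exact overlap, capped at 4 bp, between the
recipient flank boundary and the insert edge boundary at the fusion point
(suffix-vs-prefix on the left junction, prefix-vs-suffix on the right);
mismatches inside a motif are not tolerated.  Zero overlap is a blunt-end
call.  Flank windows default to 20 bp.  Flanks and insert edges are stored
in recipient orientation: the physical fusion exists only on that strand, so
the overlap is computed there, and a helper exposes the donor-oriented edge
of minus-strand inserts.  Overlaps at different lengths are not nested
(a 2 bp overlap does not imply a 3 bp test string match), so the called
length always ≥ the planted length, with equality unless flank context
happens to satisfy a longer overlap — a 1 bp chance overlap occurs at p ≈ 1/4
per side, which is why reports carry the motif and length, not just the
binary call.  Cross-species conservation is the longest boundary string
(≤ 4 bp) present as an overlap in every group member and identical across
members; exact intersection is used because the underlying comparison window
is not defined more precisely anywhere, and singleton groups are excluded.

## Repeats

`find_self_repeats` reuses the alignment engine on a genome against itself
(default gates: 100 bp, 95% identity, E ≤ 1e−5, both orientations), drops the
trivial self match and one of each mirrored duplicate (keeping the pair with
the lower-coordinate first interval), and reports the two size tiers
(> 1 kb, > 100 bp — the > 1 kb pairs are a subset of the > 100 bp count) plus
`repeat_size_bp`, the union of **all** repeat-involved intervals (both copies
of a pair; the alternative single-copy convention is not used and this choice
is stated here because published tables leave it open).

Repeat-class attribution is a library-matching stand-in for RepeatMasker:
each segment is aligned against every labelled library entry (default gates
relaxed to 50 bp / 80% identity, since library entries act as family
consensi) and takes the class of the best raw-score hit, ties broken by
higher identity, longer hit, then class name.  No-hit segments are
`unspecified` and flagged.

## Statistics

Ratio tables round half-up to two decimals to match printed precision, and
flag species below 20%.  Regression is ordinary least squares with
R² = 1 − SSres/SStot; an all-equal predictor is an error and a constant
response is defined as R² = 0 (flagged).  The group test is Welch's
unequal-variance two-tailed t-test by default — the compared groups are
wildly unequal in size (e.g. ~20 seed plants vs 2 bryophytes), where the
pooled-variance assumption is indefensible — with Student's test switchable.
Significance markers follow the ** p < 0.01 / * p < 0.05 convention.
Per-species totals are union-bp per segment class within each recipient
record (overlaps counted once), and the ±5% whisker columns in the totals
table are a display convention carried through from the figure style they
feed, not a statistic.

## Synthetic trios

The simulator is the ground-truth substrate standing in for full genome
sets, at desk scale: by default 90 kb nuclear / 45 kb mitochondrial / 20 kb
chloroplast backgrounds drawn i.i.d. at GC 0.44, with 10 numts and 10 mtpts
per trio, insert lengths log-uniform on 150–3000 bp, identity erosion 0.02
substitutions/bp (an indel option exists, default 0, so alignment oracles
stay simple), 30% of inserts reverse-complemented, junction micro-homology
lengths uniform on {0..4}, and per-gene fates drawn as 15% lost / 60% of the
rest transferred / half of the copies truncated to 30–70% removed.  Micro-
homology planting rewrites the recipient flank to match the insert edge, so
donor sequences remain pristine references; forced clade motifs rewrite both
edge and flank.  Donor intervals are drawn on pre-insertion cores and
remapped to final coordinates, and insertion points avoid embedded genes and
each other by a 60 bp margin.  Everything derives from one `numpy` generator
seeded by `SimConfig.seed`, giving byte-identical artifacts per seed, and
recipient length always equals background plus planted insert lengths.

`make_repeat_toy` builds ≤ 10 kb genomes with exact planted duplications
whose flanking bases are rewritten to *break* boundary agreement, and whose
copies are separated by ≥ 170 bp; this makes the detected pair list exactly
comparable to a seed-free O(n²) enumeration of maximal exact repeats for any
seed (no chance extensions, no merged neighbouring alignments).

What the simulator does **not** model: Markov/base-composition structure of
real genomes (backgrounds are i.i.d., adequate for gate behaviour but
optimistic for repeat false positives), phylogenetically correlated transfer
events across species (each trio is independent; shared-ancestor events are
out of scope), RNA-mediated transfer, and selection on transferred copies.
Passing benchmarks therefore demonstrate correctness of the detection and
classification machinery under controlled conditions, not sensitivity or
specificity on real chromosomes.

## Benchmark problem sizes

The recovery benchmarks use 10 trios × (10 numts + 10 mtpts) for transfer
recovery (breakpoints scored at ±5 bp), 10 species × 25 genes = 250 cells
for fate recovery, 4 species × 15 mtpts = 120 junction sides for
micro-homology calls, 3 synthetic clades for motif intersection, 2 toys for
the repeat oracle, 40 planted elements for class attribution, and 1000 null
replicates (n = 8 per group) for the Welch type-I calibration.  These sizes
were chosen so each stage exercises all planted feature types with
comfortable statistical margins while the whole benchmark completes in a few
minutes on one CPU.
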