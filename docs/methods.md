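# Methods

## Model and assumptions

`serialsv` models a locus as a sequence of *segments* and explains the
difference between a reference and a query haplotype as an ordered series of
NAHR-consistent events. The substrate assumption is that every event is
anchored on a pair of homologous repeats visible in the pairwise alignment:
a query segment aligning to two reference columns in the same orientation
licenses a deletion or duplication between those columns; opposite
orientations license an inversion. Mechanisms that do not leave such a
signature (mobile-element insertions, MMBIR/FoSTeS-style events, duplicative
transposition) are out of model and surface as `UNEXPLAINED` loci.

Events are simulated directly on the segmented dotplot by column surgery:

* `DEL(i, j)` removes columns `[i, j)` — one repeat copy survives, which
  mirrors the single chimeric repeat NAHR leaves behind;
* `DUP(i, j)` inserts a copy of columns `[i, j)` immediately before `j`;
* `INV(i, j)` reverses column order over `[i, j]` inclusive and negates the
  orientation entries in those columns.

These conventions make DEL and DUP exact inverses of each other. Column bp
lengths and per-column duplication counters travel with their columns.

## Alignment layer

The query region is split into 1 kbp chunks, each aligned separately with
all multi-mappings retained, and collinear chunk alignments are concatenated
when the end→start gap is at most 5% of the chunk length on both axes
(strand-aware: minus-strand chains have target coordinates decreasing as
query increases). When several alignments compete for the same merge
partner, the longest one (ties: smaller target start) wins; merging is run
to a fixpoint and is therefore idempotent. The built-in aligner seeds on
exact 16-mers grouped per diagonal and reports a local alignment when a
diagonal accumulates ≥ 250 seed-covered bases; divergent repeat copies down
to roughly 90% identity still produce the multi-mappings the method needs,
with fading sensitivity below ~95% — which is the intended behavior, since
repeats invisible to alignment cannot mediate recognizable NAHR. An external
minimap2 adapter (`-x asm20 -P -c -s 0 -M 0.2`) is provided for real
assemblies; the internal aligner makes all tests hermetic.

## Segmentation

Noise control has two parameters, a minimum alignment length `l` and a
rounding lattice `r`, set as a stepwise function of locus size (100 bp below
50 kbp; 1 kbp to 500 kbp; 10 kbp to 5 Mbp; 20 kbp above). After filtering,
all breakpoints are rounded to the nearest multiple of `r` (exact halves
round up) and alignments are trimmed until their slope is exactly ±1, with
zero-span leftovers dropped. Quantization is kept *consistent*: axis lengths
snap to the same lattice (so no sub-lattice remainder segment survives at
region edges), and alignment endpoints that touch a sequence boundary stay
pinned to the snapped axis end, the slope trim being taken from the interior
side (endpoints away from boundaries are trimmed at the record's end). This
boundary pinning guarantees that one bp position — in particular a sequence
end — always maps to one lattice point, which is what lets a correct
reconstruction of a locus that shrank or grew reach a perfect score instead
of stranding a phantom edge segment. Gridlines spawn from every alignment endpoint, and every
interior crossing of a gridline with an alignment spawns the perpendicular
gridline, iterated to a fixpoint (termination is guaranteed because every
cut lies on the finite lattice). If the grid exceeds the dimension caps
(rows + columns ≤ 250, alignments ≤ 150), `l` and `r` are doubled — starting
again from the raw alignments, since rounding is destructive — until the
caps are met. The resulting matrix is exact: nonzero cells, traversed
diagonally, reproduce the denoised alignment set, and every nonzero cell is
square (row length = column length).

## Scoring

Mutated matrices are scored with a greedy, linear-time segment alignment:
walking query rows in order, each row is scored by its closest
forward-matching column relative to the expected position (one past the last
matched column), contributing `1 / (1 + gap)`; rows without a match advance
the expectation by one. The total is divided by `m + n − offset_end`.
Reference column indices are taken 1-based with the offset starting at 0,
which is the convention under which a full main diagonal of a square matrix
— and only a perfect reconstruction of that form — scores exactly 1.0.
Candidate matches farther than `gap_cap` (default 20) columns from the
expected position are ignored, keeping the scan linear. A length-weighted
variant (rows and columns weighted by bp segment length) is available via
`score_matrix(..., weighted=True)` but is not the default: the unweighted
form follows the method's published recurrence literally, and the search
optimizes it.

## Search

Breadth-first over event series to `max_depth` (default 3). Heuristics:
per-column duplication budget (`max_dups`, default 2) — a DUP touching an
exhausted column is not generated; optional per-layer beam (default
unbounded); and early termination once a score-1.0 state exists, which
cannot affect the best score (the score is bounded by 1) and only truncates
the tail of the sub-optimal report list. States are deduplicated on
(entries, column lengths, duplication counters), so each distinct matrix
state is expanded once, at its shallowest depth. Layer nodes store only the
op tuples and replay them from the root on expansion; this keeps memory
proportional to the deduplication set rather than to stored matrices.
Trajectories within `report_window` (5%) of the best score are reported,
ordered by score, depth, then lexicographic ops. A locus is classified from
the best trajectory reaching `success_threshold` (default 0.98; 0.95
recommended for cross-species comparisons): REF at depth 0, SV1 at depth 1,
SSV at depth ≥ 2, otherwise UNEXPLAINED; queries without a contiguous
assembly over the locus are UNASSEMBLED.

## Whole-genome mode

Candidate ROIs come from breaks in a whole-genome alignment (minimap2
`-x asm5` when not supplied as PAF): alignments contained in another on both
axes are dropped; alignment endpoints become breakpoints, excluding contig
termini (position 0 or the contig length on either axis — assembly edges,
not SV evidence) and any breakpoint pair closer than 10 kbp in both
reference and query coordinates (small indels). Each surviving breakpoint
seeds a window of ± half the merge distance on the reference, at each of
the three merge distances (200 kbp, 1 Mbp, 5 Mbp); overlapping windows are
unioned per distance, expanded by 50% per side, and windows under 50 kbp
are discarded. The paper-stated procedure does not pin down the extent of a
window seeded by co-located breakpoints (a clean insertion leaves two
breakpoints at one reference coordinate); seeding by ± merge-distance/2 is
this package's resolution of that gap and guarantees insertions are
captured at every distance. Overlapping windows with discordant calls are
reconciled by keeping the most zoomed-in (smallest) window's call.

The locus-set builder applies, in order: SV length filter (> 10 kbp), union
with overlapping SD intervals, merging of intervals overlapping by ≥ 50% of
the smaller one (read as such because strict reciprocity is unstated;
parameterized), 25%-per-side elongation, mask subtraction (split parts are
each carried forward), < 100 kbp proximity merging, and a > 40 kbp size
filter.

## Simulator

`make_base_sequence` draws a uniform-i.i.d. background and plants SD pairs
by copying a source segment to a second position, substituting bases at rate
(1 − similarity) (substitutions never silent, so the expected Hamming
distance is exactly `L·(1 − s)`), reverse-complementing minus-orientation
copies. Copies are placed jointly by reserving lengths plus separation gaps
(default 2·SD length + 5 kbp between any two copies) and spreading the
remaining slack uniformly — exact, no rejection. Trajectories are sampled
from the events licensed by the current repeat configuration, with copy
coordinates, orientations and copy-number tracked through every event;
candidate events whose interval boundary would cut through another tracked
copy are skipped to keep that bookkeeping exact. The standard benchmark
design crosses SD lengths {0.1, 0.5, 1, 10} kbp with similarities
{90, 95, 99}%, 50 base sequences per cell and 2 derivatives each (depth
drawn uniformly from 1–3), i.e. 1200 mutated sequences; the default
background is 150 kbp, chosen to sit in the 1 kbp-resolution regime while
accommodating two 10 kbp SD pairs with their separations.

What the generator does *not* emulate: assembly errors, sequencing noise,
SNV background outside the SD copies, repeat families with more than two
initial copies, and non-NAHR rearrangements. Passing benchmarks therefore
demonstrate correct reconstruction of NAHR series from faithful assemblies,
not robustness to misassembly.

## Benchmark success and a resolution caveat

A simulated case counts as correctly reconstructed when the best recovered
trajectory reaches the success threshold (0.98) on the bp-weighted
(size-scaled) score — the scale on which the score is defined for locus
classification — while the search itself ranks candidate states by the
segment-count recurrence it optimizes. Demanding a score of exactly 1.0
instead runs into a quantization fact worth stating: event breakpoints are
arbitrary bp values, and a duplication of, say, 49,335 bp must occupy 49 or
50 segments on a 1 kbp lattice — so the two copies can never both be
represented exactly, and a correct call may top out marginally below 1.0.
On the segment-count scale this lattice-parity residue weighs one full
segment regardless of its bp size; on the bp scale it weighs what it is
(sub-lattice), which is why success is evaluated there. Large deviations
from a perfect reconstruction fail the threshold on either scale.

## Enrichment statistics

Locus-vs-feature overlap is flagged either by intersection with features
padded by a fraction of their own length (default 25%) or by locus-midpoint
(`floor((start+end)/2)`, half-open) containment, which controls for locus
size. The resulting 2×2 tables are tested with the one-sided (greater)
Fisher exact test; both the sample odds ratio `ad/bc` and the conditional
maximum-likelihood odds ratio (the estimator R's `fisher.test` reports,
maximizing Fisher's noncentral hypergeometric likelihood given the margins)
are reported, because the two differ noticeably at survey-scale counts.
Both are computed through scipy's exact routines (log-space internally) and
are cross-checked in the tests against a brute-force hypergeometric tail
sum and a likelihood grid scan.

## Numerical choices and tie-breaks

* Rounding ties (exact halves) round up; merge-competition ties go to the
  smaller target start; cell orientation conflicts go to the longer parent
  alignment, then to forward; equal-scoring trajectories order by depth,
  then lexicographic op tuples. All stages are deterministic and
  order-independent with respect to input record order.
* The simulator uses numpy's default (PCG64) generator; every consumer
  accepts either a seed or a Generator, and the benchmark derives per-case
  seeds from a single `SeedSequence`.
* Degenerate inputs: empty alignment sets yield an UNEXPLAINED call with
  score 0; an empty candidate set at depth 0 yields the single REF
  trajectory; zero-margin contingency tables return p = 1 and boundary odds
  ratios (0/∞).

## Problem sizes in the test suite

The test benchmark runs 10 replicates per design cell on 150 kbp sequences
(120 pipeline runs); the search-oracle comparison uses 200 random matrices
with ≤ 6 columns against exhaustive enumeration to depth 3; the scoring
recurrence is cross-checked on 1000 random matrices up to 10×10; the full
1200-case design is instantiated (generation only) at a 120 kbp background.

## Known limitations

* Repeats shorter than the rounding lattice are invisible unless alignment
  chaining extends through them; sub-kbp SDs are only partially recovered,
  by design of the resolution model.
* The search explains structure, not sequence identity: segment divergence
  is not part of the score, so among equal-scoring trajectories the true
  history is not necessarily ranked first.
* Exhaustive depth-3 search over repeat-dense matrices can visit millions
  of states; the duplication budget, beam width and dimension caps are the
  levers exposed to bound it.
* Locus histories more complex than three events, recurrent toggling, and
  gene conversion are outside the search horizon.
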