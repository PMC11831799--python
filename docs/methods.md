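# Methods

## The problem

All-against-all alignment of long sequencing reads is the dominant cost of
overlap-layout-consensus assembly.  `ovgraph` avoids it by treating a small
set of *seed reads* as a "virtual reference": if the seeds jointly cover
the donor genome, every other read can be connected to the graph by
mapping it onto the seeds, and seed selection can be driven by an
estimated per-read coverage so that still-uncovered genome regions recruit
new seeds in later iterations.  The output is a deliberately conservative
*core graph* of confident overlaps, optionally densified afterwards by
transitive inference.

## Iterative construction

Each iteration performs:

1. **Seed selection.**  Iteration 1 takes the `p0` (default 3%) longest
   reads.  Later iterations sample `ps` (default 10%) of the *eligible*
   reads uniformly at random, where eligible means estimated coverage
   below the adaptive threshold `T_RC` and never previously used as a
   seed.  Selected reads are admitted in selection order until the
   `batch_bases` budget binds, which is the memory-control contract: the
   index never holds more than one batch.
2. **Indexing.**  Minimizers (canonical k-mer of minimum hash in each
   window of `w_sr = 5` consecutive k-mer starts, `k = 15`) of the seed
   batch are recorded as (value, read, position, strand) quadruples,
   sorted by hash value, with a bucket table over the top `2l` bits
   (`l = 11`) for fast range lookup.  Values occurring more than
   `repeat_occ_cap = 500` times are flagged repetitive and skipped at
   query time.  Hashing uses the splitmix64 finalizer, an invertible
   64-bit mixer, over the 2-bit encoding of the lexicographically
   canonical k-mer; k-mers containing N never become minimizers.
3. **Skeleton alignment.**  Query-read minimizers are matched through the
   index; matches of one (seed, relative strand) group are merged into
   colinear match blocks (per-step diagonal drift at most
   `max_gap = 100` bp) and chained by sparse dynamic programming.  Blocks
   i → j may chain when `D_q > -k`, `D_s > -k` and
   `|D_q − D_s| < δ·min(D_q, D_s)` with `δ = 0.25`; when
   `min(D_q, D_s) ≤ 0` the third condition degenerates and is clamped to
   `|D_q − D_s| < δ·k`.  The vertex score recursion
   `S(j) = max_i S(i) + w(i→j) − p(i→j)` uses the successor's matched
   bases as the edge weight and
   `p = 0.3·|D_q − D_s| + 0.01·max(min(D_q, D_s), 0)` as the penalty, so
   cost is dominated by diagonal drift rather than plain distance.  The
   best path is removed and chaining repeats until the best remaining
   score falls below `min_skeleton_score = 30` (two anchors' worth).
4. **Confident-overlap (CRO) filtering.**  A skeleton survives when its
   implied overlap is at least `t_om = 500` bp, its non-redundant matched
   bases at least `t_nb = 100`, and neither side overhang exceeds
   `t_oh = 2000` bp; the `n_as = 2` highest-scored survivors per query
   become graph edges (one edge per read pair, higher score wins).
5. **Coverage re-estimation and stopping.**  Reads are split into
   `w_rc = 1000` bp windows.  A window is covered by a direct edge when
   the edge's interval spans at least half of it, and by an *indirect*
   read (one sharing a seed neighbour) when that read's interval on the
   shared seed, projected affinely through the connecting edge, spans at
   least half of it.  Read coverage is the mean over windows;
   `T_RC = median(coverage) × p_rc` with `p_rc = 0.5`.  Construction
   stops when fewer than `stop_fraction = 0.002` of all reads can be
   newly seeded, or after `max_iterations = 30`.

### Overhang geometry

The implied overlap extends the chained span to the nearer read end on
each side.  The per-side overhang is the extension distance itself —
`min(chain q_start, oriented chain s_start)` on the left and its mirror
on the right.  For a genuine dovetail or containment both are bounded by
the minimizer sampling granularity (a few bases, not exactly zero); a
repeat-induced overlap leaves unaligned sequence on *both* reads and
produces a large hang.  Note that a read extending past the *end* of its
partner is normal dovetail geometry and contributes nothing.

### Degenerate-median bootstrap

`T_RC` is a fraction of the median coverage, which is 0 until the graph
is reasonably dense.  A strict `coverage < T_RC` rule would then declare
no read low-covered and stall immediately, so when `T_RC = 0` the
zero-coverage reads themselves count as low-covered.

### Repeat rescue

When a query's best skeleton scores below `rescue_factor × min_skeleton_score`
and the query carries at least `rescue_min_repetitive = 5` repetitive
minimizer values, the full match set against the skeleton's seed —
repetitive values included — is re-queried, restricted to a
`rescue_band = 500` bp band around the chain's median diagonal fixed by
the unique anchors, and rechained.  The better of the old and new
skeleton is kept, so rescue never lowers a score.

## Transitive expansion

The core graph intentionally omits overlaps between two non-seed reads.
`infer_transitive` recovers them breadth-first: for every pair of reads
sharing a neighbour, the two edges' coordinate maps are composed (strand
= product of the two edge strands); the inferred geometry must pass the
same length (`t_om`) and overhang (`t_oh`) checks as a CRO.  Inferred
edges are tagged with the iteration that added them and participate in
subsequent iterations; expansion stops at a fixpoint.  Because edges are
only ever added, evaluated sensitivity is non-decreasing in the number of
iterations.

## Synthetic data

`simreads` emulates a PBSIM-style long-read experiment on a uniform
random genome (optional planted approximate repeats, destination
intervals kept disjoint from their source):

* read starts uniform along the genome with boundary clipping (a read may
  run off either end and is clipped back, keeping ≥ 500 bp), so coverage
  is flat up to the genome edges;
* lengths truncated normal — defaults 13 kb mean, 2.6 kb sd, matching a
  noisy nanopore run at the default 50× depth and 13% error split
  23:31:46 between mismatches, insertions and deletions;
* strands Bernoulli(1/2); errors applied per base after orientation;
* every read carries its exact genome placement, from which true overlap
  pairs (placement intersection strictly greater than 500 bp) are
  derived.

What the simulator does *not* model: quality scores, position- or
sequence-context-dependent error rates, chimeric reads, and long
low-complexity tracts.  Passing tests therefore demonstrate algorithmic
correctness and robustness to uniform indel-dominated noise, not
performance on pathological real-data artifacts.

## Evaluation

Precision and sensitivity are TP/reported and TP/truth over
deduplicated unordered read pairs; a reported pair is TP iff any
placement combination of its two reads intersects by > 500 bp.  Reads
that are unmapped or below `min_mapq = 10` in a pseudo-truth mapping are
ambiguous: they contribute no truth pairs and overlaps touching them are
dropped from the reported count.  R% is the fraction of truth-bearing
reads with at least one true overlap recovered; C% and Gap Num. describe
the genome covered by placements of edge-bearing reads; Con. Num. counts
connected components among edge-bearing reads.  Block-wise FPR and R%
tile the genome (1 kb blocks by default for these genome sizes); a read
belongs to every block its placement intersects.

## Misjoin postprocessing

Reads are realigned to contigs with the same minimizer/skeleton
machinery, reporting the *unextended* chain span so clipped read ends
stay visible.  Tiling 10-kb windows flag HCR (mean depth > 3×D), LCR
(mean depth < 0.15×D) and CLIP (> 60% of the window's reads clipped by
≥ 500 bp) candidates; candidates within 20 kb merge, merged regions
without a CLIP component shorter than 20 kb are dropped, CLIP-bearing
regions within 10 kb of a contig end are dropped as boundary artifacts,
and verified regions are excised (fragments < 1 kb discarded).

## Problem sizes and numerical choices

The test suite and the acceptance script run on 100-kb genomes at 30×
(~250 reads, ~3 Mb) for graph construction and a 260-kb genome for the
misjoin fixture, sizes at which exhaustive oracles (quadratic truth
enumeration, brute-force chain enumeration up to 12 blocks, per-window
minimizer scans up to 1 kb) are feasible; the algorithms themselves are
size-agnostic.  The misjoin fixture uses 16-kb reads so that a 10-kb
window at the junction is dominated by junction-spanning (hence clipped)
alignments rather than reads wholly contained beside it.  Ties are broken
deterministically throughout (leftmost minimum in minimizer windows,
smaller read id in seed selection and CRO ranking), and all randomness
flows from explicit integer seeds, which makes PAF output byte-stable.

## Known limitations

* Reads enclosed entirely in long repeats can still be placed on the
  wrong copy; the rescue band mitigates but does not eliminate this.
* Inferred (transitive) edges carry composed, rounded coordinates and no
  matched-base count; they are markers of connectivity, not alignments.
* The misjoin scanner derives depth from PAF intervals, so per-base
  depth inside an alignment is approximated as 1 (no split or
  supplementary alignments).
* Single-threaded; the batch contract bounds memory, not wall time.
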