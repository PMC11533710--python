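# Methods

## Model

The input is an MSA: m gapped rows of equal length n over {A, C, G, T, N}
plus the gap symbol `-`, with no gap-only column and (for input files) no
gap-only row.  All coordinates are 1-based with closed intervals.

A block (K, b, e) requires every row of K to spell the same gapped string on
[b, e]; its label is that string, and γ denotes the label with gaps removed.
Gaps and `N` are ordinary characters for block computation — a block may
span gap columns, which is what lets indel structure become shared nodes.

A maximal block cannot be enlarged: no outside row matches its label
(row-maximality), and its rows disagree on column b−1 and on column e+1
(left/right-maximality) unless the interval touches an alignment boundary.
Maximal blocks are enumerated by a positional-BWT-style column sweep: for
each start column the rows are partitioned by the string read so far, the
partition refining column by column; a partition class is by construction
row-maximal, and is emitted when the left/right conditions also hold.  The
sweep is O(n²·m) worst case, ample at the scale the per-window instances
reach; a brute-force enumerator (exhaust intervals, partition, filter by the
direct maximality predicate) serves as an independent oracle in the tests.

For two overlapping maximal blocks (ordered so b1 ≤ b2), the **row-maximal
decomposition** emits the remainders (K1, b1, b2−1), (K2, e1+1, e2) if
e1 < e2, and (K1, e2+1, e1) if e2 < e1 — each with an empty interval
suppressed.  The **complete decomposition** adds, for each of K1∩K2, K1∖K2
and K2∖K1 (when nonempty), candidates over [b1, e1], [b2, e2] and — when
b2 < e1 — the intersection [b2, e1].  Candidates built from row-set
differences are not guaranteed to agree outside the parent that owns their
rows, so every candidate is validated against the MSA and silently dropped
when invalid; this also means a surviving difference candidate can
legitimately cover cells outside the union of its parents (its rows simply
happen to agree there).  Decomposition is a single pass over unordered pairs
of maximal blocks; products are not re-decomposed.

## Instance construction

Column runs on which all m rows are identical are *vertical* runs.  With
forcing parameter α, every column-maximal vertical run of width ≥ α is
forced into the cover and removed from the optimization; the remaining
column windows are solved independently (their candidate sets are built per
window, so a larger α genuinely changes the search space rather than merely
re-partitioning it).  `alpha=None` ("disabled") forces nothing.  A numeric α
is literal: a full-width vertical run still qualifies at α ≤ n.  The
`breakpoints` report tabulates the longest free window as a step function of
α (change points sit one past each distinct run width), which is how a user
sizes α against available solver capacity.

Each window's candidate set is: its ≥2-row maximal blocks (one-row maximal
blocks encode a whole private segment and are deliberately excluded), their
pairwise decomposition, one-row blocks ({r}, b, e) on each maximal interval
of row r not covered by any ≥2-row *maximal* block (coverage is judged
against the maximal blocks, not the decomposed set), and one-character
blocks (K_σ, b, b) for every column b and every character σ present in it
(gap included; at most 6 per column).  The one-character blocks partition
every column, so every instance is feasible by construction.

## Solving

One binary variable per candidate, one equality constraint per window cell.
Backend: HiGHS via `scipy.optimize.milp` — deterministic for a fixed
variable order (candidates are kept sorted by (b, e, min K)); a
`solver_seed` argument is accepted for interface stability but is not
consumed by the backend.  Every returned cover is re-verified cell by cell
and its objective recomputed from the block costs (agreement tolerance
1e-6); a solver "infeasible" status is raised as an internal error because
feasibility is guaranteed.  When a time limit cuts the solve short the
incumbent is returned flagged non-optimal.

Objective parameters and defaults: q = 20 (the weighted objective penalises
blocks whose gap-free label has length ≤ q — the comparison applies to the
label length, not the column span), Δ = 1000 (penalty weight, > 1 unless
explicitly set to 1 to disable penalisation), p = 0.11 (the depth objective
penalises blocks with |K| ≤ ⌊p·m⌋; an alternate `depth_min_count` mode
applies a literal row-count threshold).  These defaults match the regime the
method was designed for — panels of tens of near-identical genomes with a
seed length of 20 used by graph aligners.  Fractional costs
(penalized-strings) are floats; ties between optimal covers may be broken
either way by the solver, so only the optimal objective *value* is
guaranteed deterministic, and tests compare values, never specific covers.

Two exhaustive oracles back the ILP in the tests: a depth-first
exact-cover search with memoisation over the same candidate set (≤ 30
cells), and the same search over *all* blocks of the alignment (≤ 20
cells), whose optimum lower-bounds any restricted candidate set.

## Graph construction and post-processing

One node per cover block (ids assigned by sorting blocks by (b, e, min K)),
walks follow each row's blocks in column order, and the arc set is exactly
the walk-consecutive pairs — equivalent, for an exact cover, to the rule
"adjacent intervals sharing a row", and maintained under post-processing
where dangling adjacencies would otherwise be ambiguous.  Post-processing:
(1) remove nodes whose label is entirely gaps, splicing walks past them;
(2) strip gaps from the remaining labels (no label can become empty — it
would have been gap-only); (3) repeatedly merge an arc (u, v) with
outdegree(u) = 1, indegree(v) = 1, no walk ending at u and no walk starting
at v, keeping the smaller id.  The two extra guards are not part of the
usual "collapse non-branching paths" phrasing but are required: without
them a walk terminating mid-chain would lose its endpoint and losslessness
would break.  Both graphs (raw and post-processed) are DAGs; the pipeline
asserts losslessness after each stage.

GFA1 output: `H VN:Z:1.0`, one `S` line per node, `L` lines with overlap
`0M`, `P` lines (one per input sequence, duplicate names suffixed `.2`,
`.3`, …, all orientations `+`).  Metrics: node count; total label length;
potential seeds of length k = 20 (positional count Σ max(0, |label|−k+1) by
default — seeding tools consume occurrence positions — with a distinct-k-mer
mode selectable, since either reading of "k-mers that are a substring of a
node label" is defensible); nodes traversed by ≥ ⌈t·#walks⌉ walks
(default t = 0.11) and by all walks.

## Synthetic data

The simulator emulates a panel of closely related genomes: a random ancestor
(default 200 bp) copied to m rows (default 10), per-site substitutions
(default 1%) and indel events (default 0.5%, length ≤ 3) applied outside
designated shared segments, with gaps planted directly as alignment columns.
Because there is no realignment step the ground truth is exact: planted
all-row shared segments surface as vertical runs and maximal blocks.  What
the simulator does *not* model: realignment artefacts (gap placement chosen
by an aligner's objective, which can shift block boundaries), rate
heterogeneity, recombination and large structural variants — so passing
tests demonstrate correctness of the cover/graph machinery on clean
alignments, not robustness to aligner idiosyncrasies.  All-gap columns
arising from coincident deletions are dropped; a draw that empties a row is
retried with a derived seed.

## Problem sizes used in the checks

The test battery and the acceptance script run the full pipeline on
simulated alignments of 2–8 rows and ≤ 60 columns (100 alignments in the
test suite, 40 in the script), which keeps every ILP at a few hundred
constraints and the complete-decomposition candidate sets in the low
thousands — large enough to exercise window splitting, both decompositions
and all five objectives, while the whole battery solves in well under a
minute.  Oracle comparisons use ≤ 3×4 alignments, the largest size at which
the all-blocks search is instant.

## Known limitations

- The ILP grows quickly with the complete decomposition; genome-scale use
  relies on α-splitting to keep windows small, and very wide windows may
  need a time limit (returning a feasible, possibly suboptimal cover).
- Only single-strand, acyclic graphs are produced; no reverse complements.
- The alphabet is fixed to DNA plus `N` and `-`.
- One-row maximal blocks are always excluded from candidates; an input whose
  rows share nothing therefore covers each private stretch with one-row
  fallback blocks rather than with maximal blocks.
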