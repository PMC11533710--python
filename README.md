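# blockgraph

Build an **acyclic pangenome variation graph** from a multiple sequence
alignment (MSA) by solving a **minimum-weight exact block cover** with
integer linear programming.

Given an alignment of closely related genomes (e.g. viral isolates), a
*block* (K, b, e) is a set of rows K and a column interval [b, e] on which
all rows of K spell the same gapped string.  An *exact cover* is a set of
pairwise non-overlapping blocks covering every alignment cell exactly once.
Each cover block becomes a graph node labelled by the block's string; blocks
on consecutive column intervals sharing a row are joined by an arc, and each
input sequence traces one walk through the graph.  By construction the graph
is a lossless representation of the alignment: concatenating the labels along
a walk (and deleting gaps) reproduces the input sequence exactly.

The cover is chosen by an ILP — one binary variable C[K, b, e] per candidate
block, one equality constraint per MSA cell:

```
min  Σ  w(K,b,e) · C[K,b,e]
s.t. Σ_{(K,b,e): r∈K, b≤c≤e}  C[K,b,e] = 1   for every cell (r, c)
```

with five selectable weight functions: **blocks** (w = 1, fewest nodes),
**weighted** (w = Δ if the gap-free label length |γ| ≤ q, else 1 — prefer
long labels), **depth** (w = Δ if |K| ≤ ⌊p·m⌋, else 1 — prefer high-coverage
nodes), **strings** (w = |γ|, shortest total graph), and
**penalized-strings** (w = |γ|/|K|).

Candidates are not all blocks (exponentially many) but: the maximal blocks
of the alignment, the products of decomposing each overlapping pair of
maximal blocks (a fast *row-maximal* or a richer *complete* strategy),
one-row blocks on uncovered stretches, and one-character blocks per column —
the last group partitions every column, guaranteeing feasibility.  Column
runs on which *all* rows agree ("vertical blocks") of width ≥ α are forced
into the cover and split the alignment into independently solved windows.
The graph is post-processed (gap-only nodes removed, gaps stripped from
labels, non-branching chains collapsed) and written as GFA1 with one P line
per input sequence.

The MILP backend is HiGHS via `scipy.optimize.milp`.

## Worked example

```python
from blockgraph import (running_example, run_pipeline, ObjectiveSpec,
                        compute_metrics, write_gfa)

msa = running_example()          # 5 sequences x 9 columns
res = run_pipeline(msa, ObjectiveSpec("blocks"), alpha=2,
                   strategy="row-maximal")
print(res.cover.objective_value)           # 16.0  (blocks in the cover)
m = compute_metrics(res.graph, k=3)
print(m.n_nodes, m.total_label_length, m.all_sequences_nodes)  # 12 14 3
write_gfa(res.graph, "example.gfa")
```

The cover uses 16 blocks (including the forced vertical block on columns
7–8, shared by all five sequences); after post-processing the graph has 12
nodes totalling 14 label characters, 3 of which are traversed by every
sequence.  Each of the 5 walks in `example.gfa` spells its input sequence.

The same pipeline is available from the shell:

```bash
blockgraph build example.fa --objective blocks --alpha 2 \
    --decomposition row-maximal --out-dir out/
blockgraph breakpoints example.fa   # alpha vs. longest solvable window
blockgraph blocks example.fa        # maximal-block dump
blockgraph metrics out/graph.gfa --k 20
```

## Layout

- `src/blockgraph/msa_io.py` — aligned-FASTA reading/validation, 1-based indexing
- `src/blockgraph/blocks.py` — block algebra, maximal-block enumeration + brute-force oracle
- `src/blockgraph/decomposition.py` — row-maximal and complete pair decomposition
- `src/blockgraph/instance_builder.py` — vertical-block forcing, window splitting, candidate completion
- `src/blockgraph/mwbc_solver.py` — the exact-cover ILP, objectives, exhaustive oracles
- `src/blockgraph/graph_builder.py` — graph construction and post-processing
- `src/blockgraph/gfa_metrics.py` — GFA1 output and evaluation metrics
- `src/blockgraph/synthetic_fixtures.py` — planted-block MSA simulator and the worked example
- `src/blockgraph/pipeline.py`, `src/blockgraph/cli.py` — orchestration and CLI

See `docs/methods.md` for the model, parameters and design choices.
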