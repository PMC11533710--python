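"""From a global exact cover to a variation graph, plus post-processing.

Each cover block becomes a node labelled by the block's gapped string; two
nodes are joined by an arc when their blocks sit on consecutive column
intervals and share a row — equivalently, when they appear consecutively on
some row's walk.  Each input row yields one walk (its cover blocks in column
order), so concatenating walk labels and deleting gaps reproduces the input
sequence exactly: the graph is a lossless representation of the MSA.

Post-processing then (1) removes nodes labelled entirely by gaps, rewiring
walks past them, (2) strips gaps from the remaining labels, and (3) collapses
non-branching chains into single nodes.  The collapse additionally requires
that no walk ends at the upstream node or starts at the downstream node,
which is what preserves walk semantics (and hence losslessness) when a walk
terminates mid-chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .blocks import Block, label
from .msa_io import GAP, MSA, ungapped
from .mwbc_solver import Cover, verify_exact_cover


@dataclass
class VariationGraph:
    """A labelled DAG with one distinguished walk per input sequence."""

    labels: dict[int, str]
    arcs: set[tuple[int, int]]
    walks: list[list[int]]
    walk_names: list[str]

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def walk_label(self, i: int) -> str:
        """Concatenated node labels of walk ``i`` (0-based), gaps removed."""
        return "".join(self.labels[v] for v in self.walks[i]).replace(GAP, "")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.labels)
        g.add_edges_from(self.arcs)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())


def _arcs_from_walks(walks: Iterable[list[int]]) -> set[tuple[int, int]]:
    return {
        (w[i], w[i + 1]) for w in walks for i in range(len(w) - 1)
    }


def build_graph(msa: MSA, cover: Cover | Iterable[Block]) -> VariationGraph:
    """One node per cover block; walks follow each row's blocks in column
    order; arcs are exactly the walk-consecutive pairs (equivalently: blocks
    on adjacent intervals sharing a row)."""
    blocks = tuple(cover.blocks) if isinstance(cover, Cover) else tuple(cover)
    verify_exact_cover(msa, blocks)
    ordered = sorted(blocks)
    node_of = {blk: i for i, blk in enumerate(ordered, start=1)}
    labels = {node_of[blk]: label(msa, blk).gapped for blk in ordered}
    walks: list[list[int]] = []
    for r in range(1, msa.m + 1):
        mine = sorted(blk for blk in ordered if r in blk.K)
        walks.append([node_of[blk] for blk in mine])
    return VariationGraph(
        labels=labels,
        arcs=_arcs_from_walks(walks),
        walks=walks,
        walk_names=list(msa.row_ids),
    )


def _remove_gap_nodes(graph: VariationGraph) -> VariationGraph:
    gap_nodes = {v for v, lab in graph.labels.items() if set(lab) == {GAP}}
    labels = {v: lab for v, lab in graph.labels.items() if v not in gap_nodes}
    walks = [[v for v in w if v not in gap_nodes] for w in graph.walks]
    return VariationGraph(labels, _arcs_from_walks(walks), walks, graph.walk_names)


def _strip_gaps(graph: VariationGraph) -> VariationGraph:
    labels = {v: lab.replace(GAP, "") for v, lab in graph.labels.items()}
    return VariationGraph(labels, set(graph.arcs), [list(w) for w in graph.walks],
                          graph.walk_names)


def _collapse_unipaths(graph: VariationGraph) -> VariationGraph:
    labels = dict(graph.labels)
    walks = [list(w) for w in graph.walks]
    while True:
        arcs = _arcs_from_walks(walks)
        outdeg: dict[int, int] = {v: 0 for v in labels}
        indeg: dict[int, int] = {v: 0 for v in labels}
        for u, v in arcs:
            outdeg[u] += 1
            indeg[v] += 1
        ends = {w[-1] for w in walks if w}
        starts = {w[0] for w in walks if w}
        merge: tuple[int, int] | None = None
        for u, v in sorted(arcs):
            if outdeg[u] == 1 and indeg[v] == 1 and u not in ends and v not in starts:
                merge = (u, v)
                break
        if merge is None:
            break
        u, v = merge
        keep = min(u, v)
        labels[keep] = labels[u] + labels[v]
        for other in (u, v):
            if other != keep:
                del labels[other]
        for w in walks:
            out: list[int] = []
            i = 0
            while i < len(w):
                if i + 1 < len(w) and w[i] == u and w[i + 1] == v:
                    out.append(keep)
                    i += 2
                else:
                    out.append(w[i])
                    i += 1
            w[:] = out
    return VariationGraph(labels, _arcs_from_walks(walks), walks, graph.walk_names)


def postprocess(graph: VariationGraph) -> VariationGraph:
    """Gap-only node removal, label gap-stripping, unipath collapse — in that
    order, so no empty label can survive (an emptied label was gap-only and
    its node already removed)."""
    return _collapse_unipaths(_strip_gaps(_remove_gap_nodes(graph)))


def check_lossless(msa: MSA, graph: VariationGraph) -> None:
    """Raise unless every walk spells its input sequence exactly."""
    for i in range(msa.m):
        want = ungapped(msa, i + 1)
        got = graph.walk_label(i)
        if want != got:
            raise AssertionError(
                f"row {i + 1}: walk spells {got!r}, expected {want!r}"
            )
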