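"""GFA1 serialization and graph evaluation metrics.

The graph is written as GFA1: one ``S`` line per node, one ``L`` line per arc
(overlap ``0M``; all orientations ``+`` since the graph comes from a
single-strand alignment), and one ``P`` line per input-sequence walk.
Duplicate walk names get a numeric suffix.

Metrics summarise how usable the graph is downstream: node count, total
label length, the number of potential k-mer seeds (default ``k=20``; the
positional count ``sum(max(0, |label|-k+1))`` by default, or the number of
distinct k-mers), and node-depth counts (nodes traversed by at least a given
fraction of the walks, and by all walks).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal

from .graph_builder import VariationGraph

SeedMode = Literal["positions", "distinct"]


@dataclass(frozen=True)
class GraphMetrics:
    n_nodes: int
    total_label_length: int
    potential_seeds: int
    depth_fraction_nodes: int
    all_sequences_nodes: int
    k: int
    depth_threshold: float
    seed_mode: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_tsv(self) -> str:
        d = asdict(self)
        keys = list(d)
        return (
            "\t".join(keys) + "\n" + "\t".join(str(d[k]) for k in keys) + "\n"
        )


def _unique_names(names: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for name in names:
        seen[name] = seen.get(name, 0) + 1
        out.append(name if seen[name] == 1 else f"{name}.{seen[name]}")
    return out


def write_gfa(graph: VariationGraph, path: str | Path) -> None:
    """Serialize a post-processed graph as GFA1 (H, S, L, P lines)."""
    lines = ["H\tVN:Z:1.0"]
    for v in sorted(graph.labels):
        lines.append(f"S\t{v}\t{graph.labels[v]}")
    for u, v in sorted(graph.arcs):
        lines.append(f"L\t{u}\t+\t{v}\t+\t0M")
    for name, walk in zip(_unique_names(graph.walk_names), graph.walks):
        segs = ",".join(f"{v}+" for v in walk)
        lines.append(f"P\t{name}\t{segs}\t*")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gfa(path: str | Path) -> VariationGraph:
    """Parse a GFA1 file written by :func:`write_gfa` back into a graph."""
    labels: dict[int, str] = {}
    arcs: set[tuple[int, int]] = set()
    walks: list[list[int]] = []
    names: list[str] = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("H"):
            continue
        fields = line.split("\t")
        if fields[0] == "S":
            labels[int(fields[1])] = fields[2]
        elif fields[0] == "L":
            arcs.add((int(fields[1]), int(fields[3])))
        elif fields[0] == "P":
            names.append(fields[1])
            segs = fields[2]
            walks.append(
                [int(s.rstrip("+-")) for s in segs.split(",")] if segs else []
            )
    return VariationGraph(labels, arcs, walks, names)


def compute_metrics(
    graph: VariationGraph,
    k: int = 20,
    depth_threshold: float = 0.11,
    seed_mode: SeedMode = "positions",
) -> GraphMetrics:
    """Evaluate a post-processed graph (labels must be gap-free)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 < depth_threshold <= 1:
        raise ValueError("depth_threshold must be in (0, 1]")
    labels = graph.labels
    total = sum(len(lab) for lab in labels.values())
    if seed_mode == "positions":
        seeds = sum(max(0, len(lab) - k + 1) for lab in labels.values())
    elif seed_mode == "distinct":
        kmers: set[str] = set()
        for lab in labels.values():
            kmers.update(lab[i : i + k] for i in range(len(lab) - k + 1))
        seeds = len(kmers)
    else:
        raise ValueError(f"unknown seed_mode {seed_mode!r}")
    n_walks = len(graph.walks)
    walk_count = {v: 0 for v in labels}
    for w in graph.walks:
        for v in set(w):
            walk_count[v] += 1
    need = math.ceil(depth_threshold * n_walks)
    depth_nodes = sum(1 for v in labels if walk_count[v] >= need)
    all_nodes = sum(1 for v in labels if walk_count[v] == n_walks)
    return GraphMetrics(
        n_nodes=len(labels),
        total_label_length=total,
        potential_seeds=seeds,
        depth_fraction_nodes=depth_nodes,
        all_sequences_nodes=all_nodes,
        k=k,
        depth_threshold=depth_threshold,
        seed_mode=seed_mode,
    )
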