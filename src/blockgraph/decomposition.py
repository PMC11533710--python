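"""Decomposition of pairs of overlapping maximal blocks into smaller blocks.

Two strategies produce candidate blocks for the exact-cover ILP:

* **row-maximal** — keeps each parent's full row set and cuts away the column
  overlap, yielding at most three non-overlapping remainder blocks per pair;
* **complete** — additionally generates blocks on the intersection columns
  from the row-set intersection and differences, a strict superset of the
  row-maximal output.

Candidates built from row-set differences are not guaranteed to spell a
common string outside the parent's interval; every candidate is therefore
validated against the MSA and silently dropped when invalid, so only true
blocks ever reach the solver.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Literal

from .blocks import Block, is_block, make_block, overlaps
from .msa_io import MSA

Strategy = Literal["row-maximal", "complete"]

STRATEGIES: tuple[str, ...] = ("row-maximal", "complete")


def _ordered(l1: Block, l2: Block) -> tuple[Block, Block]:
    if not overlaps(l1, l2):
        raise ValueError(f"blocks {l1} and {l2} do not overlap")
    # the b2 < b1 case is symmetric: reorder so b1 <= b2
    return (l1, l2) if l1.b <= l2.b else (l2, l1)


def row_maximal_decompose(msa: MSA, l1: Block, l2: Block) -> set[Block]:
    """Remainder blocks of an overlapping pair, keeping full parent row sets.

    With ``b1 <= b2`` the pieces are ``(K1, b1, b2-1)`` when ``b1 < b2``,
    ``(K2, e1+1, e2)`` when ``e1 < e2``, and ``(K1, e2+1, e1)`` when
    ``e2 < e1``; each piece lies inside its parent's interval, so all are
    valid blocks.  More than one piece may exist; the pieces are pairwise
    non-overlapping.
    """
    l1, l2 = _ordered(l1, l2)
    out: set[Block] = set()
    if l1.b < l2.b:
        out.add(make_block(msa, l1.rows, l1.b, l2.b - 1))
    if l1.e < l2.e:
        out.add(make_block(msa, l2.rows, l1.e + 1, l2.e))
    if l2.e < l1.e:
        out.add(make_block(msa, l1.rows, l2.e + 1, l1.e))
    return out


def complete_decompose(msa: MSA, l1: Block, l2: Block) -> set[Block]:
    """Row-maximal pieces plus intersection-column blocks.

    With ``b1 <= b2``, the extra candidates are built from the row sets
    ``K1 ∩ K2``, ``K1 \\ K2`` and ``K2 \\ K1`` over the parents' intervals
    ``[b1, e1]`` and ``[b2, e2]``, and — when ``b2 < e1`` — over the column
    intersection ``[b2, e1]``.  Candidates that are not valid blocks of the
    MSA (the rows disagree somewhere) are discarded.
    """
    l1, l2 = _ordered(l1, l2)
    out = row_maximal_decompose(msa, l1, l2)
    k1, k2 = l1.K, l2.K
    row_sets = [k1 & k2, k1 - k2, k2 - k1]
    intervals = [(l1.b, l1.e), (l2.b, l2.e)]
    if l2.b < l1.e:
        intervals.append((l2.b, l1.e))
    for ks in row_sets:
        if not ks:
            continue
        for b, e in intervals:
            if is_block(msa, ks, b, e):
                out.add(make_block(msa, ks, b, e))
    return out


def decompose_pair(
    msa: MSA, l1: Block, l2: Block, strategy: Strategy
) -> set[Block]:
    if strategy == "row-maximal":
        return row_maximal_decompose(msa, l1, l2)
    if strategy == "complete":
        return complete_decompose(msa, l1, l2)
    raise ValueError(f"unknown decomposition strategy {strategy!r}")


def decompose_all(
    msa: MSA, maximal: Iterable[Block], strategy: Strategy
) -> list[Block]:
    """Single pass over every unordered pair of overlapping maximal blocks.

    Returns the maximal blocks plus all pairwise decomposition products,
    deduplicated and sorted.  Products are not themselves decomposed.
    """
    maximal = sorted(set(maximal))
    out: set[Block] = set(maximal)
    for l1, l2 in combinations(maximal, 2):
        if overlaps(l1, l2):
            out |= decompose_pair(msa, l1, l2, strategy)
    return sorted(out)
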