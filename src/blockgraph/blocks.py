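"""Block algebra over an MSA.

A *block* ``(K, b, e)`` is a nonempty set of rows ``K`` and a closed column
interval ``[b, e]`` on which every row of ``K`` spells the same gapped string.
A block is *maximal* when it cannot be enlarged: no outside row matches its
label (row-maximality), and the rows of ``K`` disagree just before ``b`` and
just after ``e`` (left/right-maximality), unless the interval already touches
an MSA boundary.

Maximal blocks are the seeds of the whole pipeline: the gap symbol ``-`` and
``N`` are treated as ordinary characters here, so blocks may span gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .msa_io import GAP, MSA, msa_slice


class NotABlockError(ValueError):
    """The given rows do not spell a common string on the given interval."""


@dataclass(frozen=True, order=True)
class Block:
    """A block ``(K, b, e)``; ``rows`` is the sorted tuple of 1-based indices.

    Ordering is by ``(b, e, rows)``, which gives the deterministic output
    order used throughout the package.
    """

    b: int
    e: int
    rows: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise NotABlockError("K must be nonempty")
        if tuple(sorted(set(self.rows))) != self.rows:
            object.__setattr__(self, "rows", tuple(sorted(set(self.rows))))
        if not 1 <= self.b <= self.e:
            raise NotABlockError(f"invalid interval [{self.b}, {self.e}]")

    @property
    def K(self) -> frozenset[int]:
        return frozenset(self.rows)

    @property
    def width(self) -> int:
        return self.e - self.b + 1

    def cells(self) -> Iterable[tuple[int, int]]:
        """All MSA cells ``(row, column)`` the block covers."""
        for r in self.rows:
            for c in range(self.b, self.e + 1):
                yield (r, c)

    def __repr__(self) -> str:  # ({2,3,4},2,9)
        return f"({{{','.join(map(str, self.rows))}}},{self.b},{self.e})"


@dataclass(frozen=True)
class BlockLabel:
    """The label of a block: the common gapped string and its gap-free form."""

    gapped: str
    ungapped: str

    @property
    def ungapped_length(self) -> int:
        return len(self.ungapped)


def make_block(msa: MSA, K: Iterable[int], b: int, e: int) -> Block:
    """Construct ``(K, b, e)``, verifying that all rows of ``K`` agree on [b, e]."""
    rows = tuple(sorted(set(K)))
    if not rows:
        raise NotABlockError("K must be nonempty")
    if rows[0] < 1 or rows[-1] > msa.m:
        raise IndexError(f"row set {rows} out of range [1, {msa.m}]")
    if not 1 <= b <= e <= msa.n:
        raise IndexError(f"interval [{b}, {e}] out of range [1, {msa.n}]")
    ref = msa_slice(msa, rows[0], b, e)
    for r in rows[1:]:
        if msa_slice(msa, r, b, e) != ref:
            raise NotABlockError(
                f"rows {rows[0]} and {r} disagree on columns [{b}, {e}]"
            )
    return Block(b, e, rows)


def is_block(msa: MSA, K: Iterable[int], b: int, e: int) -> bool:
    """True iff ``(K, b, e)`` is a valid block of ``msa``."""
    try:
        make_block(msa, K, b, e)
    except (NotABlockError, IndexError):
        return False
    return True


def label(msa: MSA, block: Block) -> BlockLabel:
    """The block's label; independent of which row of ``K`` is read."""
    gapped = msa_slice(msa, block.rows[0], block.b, block.e)
    return BlockLabel(gapped, gapped.replace(GAP, ""))


def overlaps(b1: Block, b2: Block) -> bool:
    """True iff the row sets intersect and the column intervals intersect."""
    if max(b1.b, b2.b) > min(b1.e, b2.e):
        return False
    return not b1.K.isdisjoint(b2.K)


def is_maximal(msa: MSA, block: Block) -> bool:
    """Direct check of row-, left- and right-maximality."""
    lab = msa_slice(msa, block.rows[0], block.b, block.e)
    inside = set(block.rows)
    for h in range(1, msa.m + 1):
        if h not in inside and msa_slice(msa, h, block.b, block.e) == lab:
            return False  # an outside row matches the label
    if block.b > 1:
        prev = {msa.rows[r - 1][block.b - 2] for r in block.rows}
        if len(prev) == 1:
            return False  # extensible to the left
    if block.e < msa.n:
        nxt = {msa.rows[r - 1][block.e] for r in block.rows}
        if len(nxt) == 1:
            return False  # extensible to the right
    return True


def enumerate_maximal_blocks(msa: MSA, min_rows: int = 2) -> list[Block]:
    """All maximal blocks with ``|K| >= min_rows``, sorted by ``(b, e, min K)``.

    Column-sweep by partition refinement: for each start column ``b`` the rows
    are partitioned by the string they spell on ``[b, e]``, refining the
    partition as ``e`` grows.  A partition class is by construction the
    complete set of rows spelling its string (row-maximality is automatic);
    a class is emitted when it is also left- and right-maximal.  Classes that
    fall below ``min_rows`` can never regrow and are pruned.
    """
    if min_rows not in (1, 2):
        raise ValueError("min_rows must be 1 or 2")
    rows = msa.rows
    m, n = msa.m, msa.n
    out: set[Block] = set()
    for b0 in range(n):  # 0-based start column
        classes: list[list[int]] = []
        by_char: dict[str, list[int]] = {}
        for r in range(m):
            by_char.setdefault(rows[r][b0], []).append(r)
        classes = [c for c in by_char.values() if len(c) >= min_rows]
        e0 = b0
        while classes:
            for c in classes:
                if b0 > 0 and len({rows[r][b0 - 1] for r in c}) == 1:
                    left_ok = False  # extensible left: a wider block exists
                else:
                    left_ok = True
                if e0 < n - 1 and len({rows[r][e0 + 1] for r in c}) == 1:
                    right_ok = False
                else:
                    right_ok = True
                if left_ok and right_ok:
                    out.add(Block(b0 + 1, e0 + 1, tuple(r + 1 for r in c)))
            if e0 == n - 1:
                break
            refined: list[list[int]] = []
            for c in classes:
                groups: dict[str, list[int]] = {}
                for r in c:
                    groups.setdefault(rows[r][e0 + 1], []).append(r)
                refined.extend(g for g in groups.values() if len(g) >= min_rows)
            classes = refined
            e0 += 1
    return sorted(out)


def brute_force_maximal_blocks(msa: MSA, min_rows: int = 2) -> list[Block]:
    """Oracle enumerator: exhaust every column interval, partition the rows by
    the string they spell on it, and keep the classes passing :func:`is_maximal`.

    Guarded to tiny alignments (``m * n <= 200``): quadratic in ``n`` with a
    full maximality check per candidate.
    """
    if msa.m * msa.n > 200:
        raise ValueError("instance too large for the brute-force oracle")
    out: set[Block] = set()
    for b in range(1, msa.n + 1):
        for e in range(b, msa.n + 1):
            groups: dict[str, list[int]] = {}
            for r in range(1, msa.m + 1):
                groups.setdefault(msa_slice(msa, r, b, e), []).append(r)
            for rows in groups.values():
                if len(rows) < min_rows:
                    continue
                cand = Block(b, e, tuple(rows))
                if is_maximal(msa, cand):
                    out.add(cand)
    return sorted(out)


def blocks_tsv(msa: MSA, blocks: Sequence[Block], origin: str | None = None) -> str:
    """Tab-separated dump ``b e rows label [origin]`` for inspection."""
    lines = []
    header = "b\te\trows\tlabel" + ("\torigin" if origin is not None else "")
    lines.append(header)
    for blk in sorted(blocks):
        fields = [
            str(blk.b),
            str(blk.e),
            ",".join(map(str, blk.rows)),
            label(msa, blk).gapped,
        ]
        if origin is not None:
            fields.append(origin)
        lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"
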