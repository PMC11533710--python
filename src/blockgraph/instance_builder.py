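"""Assembling exact-cover instances from an MSA.

Column runs on which *all* rows agree ("vertical" runs) of length at least
``alpha`` are forced straight into the cover; they split the alignment into
independent sub-alignment windows.  Each free window gets its own candidate
block set: the >=2-row maximal blocks of the window, their pairwise
decomposition, one-row blocks on the stretches no maximal block touches, and
one-character blocks on every column.  The one-character blocks partition
every column by character, so each instance always contains a feasible exact
cover.

``alpha=None`` disables vertical-block forcing entirely (one window spanning
the whole alignment); a numeric ``alpha`` is applied literally, so even a
single full-width vertical run qualifies at ``alpha <= n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

from .blocks import Block, enumerate_maximal_blocks
from .decomposition import Strategy, decompose_all
from .msa_io import MSA


@dataclass(frozen=True)
class SubMSAWindow:
    """A column interval of the global alignment, either forced or free."""

    start: int
    end: int
    role: Literal["forced-vertical", "free"]

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass
class MWBCInstance:
    """One solver instance: a window sub-alignment and its candidate blocks.

    ``offset`` maps window-local column ``c`` to global column ``c + offset``.
    Candidates are in window-local coordinates.
    """

    msa: MSA
    offset: int
    candidates: tuple[Block, ...]
    alpha: int | None = None


@dataclass
class BuildResult:
    """Per-window instances plus the globally forced vertical blocks."""

    instances: list[MWBCInstance]
    forced: list[Block]
    windows: list[SubMSAWindow] = field(default_factory=list)


def find_vertical_blocks(msa: MSA, alpha: int | None) -> list[Block]:
    """Column-maximal runs where all ``m`` rows are identical, of width >= alpha.

    ``alpha=None`` (forcing disabled) returns the empty list.
    """
    if alpha is None:
        return []
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    all_rows = tuple(range(1, msa.m + 1))
    out: list[Block] = []
    run_start: int | None = None
    for j in range(1, msa.n + 2):
        uniform = j <= msa.n and len(set(msa.column(j))) == 1
        if uniform and run_start is None:
            run_start = j
        elif not uniform and run_start is not None:
            if j - run_start >= alpha:
                out.append(Block(run_start, j - 1, all_rows))
            run_start = None
    return out


def split_by_vertical(msa: MSA, forced: Iterable[Block]) -> list[SubMSAWindow]:
    """Ordered partition of ``[1, n]`` into forced and free windows."""
    forced = sorted(forced)
    windows: list[SubMSAWindow] = []
    pos = 1
    for blk in forced:
        if blk.b > pos:
            windows.append(SubMSAWindow(pos, blk.b - 1, "free"))
        windows.append(SubMSAWindow(blk.b, blk.e, "forced-vertical"))
        pos = blk.e + 1
    if pos <= msa.n:
        windows.append(SubMSAWindow(pos, msa.n, "free"))
    return windows


def longest_free_window(msa: MSA, alpha: int | None) -> int:
    """Width of the widest free window once vertical runs >= alpha are forced."""
    windows = split_by_vertical(msa, find_vertical_blocks(msa, alpha))
    free = [w.width for w in windows if w.role == "free"]
    return max(free, default=0)


def breakpoints(msa: MSA) -> list[tuple[int, int]]:
    """The step function ``alpha -> longest_free_window`` as its change points.

    Returns ``[(alpha, value), ...]`` sorted by alpha, starting at alpha=1 and
    listing each alpha at which the value changes.  The candidate change
    points are one past each vertical-run length, so the full function is
    recovered without sweeping every alpha.
    """
    run_lengths = sorted(
        {blk.width for blk in find_vertical_blocks(msa, alpha=1)}
    )
    candidates = [1] + [w + 1 for w in run_lengths]
    out: list[tuple[int, int]] = []
    prev: int | None = None
    for a in candidates:
        val = longest_free_window(msa, a)
        if val != prev:
            out.append((a, val))
            prev = val
    return out


def one_row_blocks(msa: MSA, coverage: Iterable[Block]) -> list[Block]:
    """Blocks ``({r}, b, e)`` on each maximal row interval not covered by
    any block of ``coverage`` (the >=2-row maximal blocks)."""
    covered: list[set[int]] = [set() for _ in range(msa.m + 1)]
    for blk in coverage:
        for r in blk.rows:
            covered[r].update(range(blk.b, blk.e + 1))
    out: list[Block] = []
    for r in range(1, msa.m + 1):
        start: int | None = None
        for c in range(1, msa.n + 2):
            if c <= msa.n and c not in covered[r]:
                if start is None:
                    start = c
            elif start is not None:
                out.append(Block(start, c - 1, (r,)))
                start = None
    return out


def one_character_blocks(msa: MSA) -> list[Block]:
    """Blocks ``(K_sigma, b, b)`` for each column ``b`` and each character
    (gap included) present in it; these alone partition every column."""
    out: list[Block] = []
    for b in range(1, msa.n + 1):
        col = msa.column(b)
        groups: dict[str, list[int]] = {}
        for r, ch in enumerate(col, start=1):
            groups.setdefault(ch, []).append(r)
        for rows in groups.values():
            out.append(Block(b, b, tuple(rows)))
    return out


def add_short_blocks(
    msa: MSA,
    candidates: Iterable[Block],
    coverage: Iterable[Block] | None = None,
) -> list[Block]:
    """Complete a candidate set with one-row and one-character blocks.

    One-row-block coverage is judged against ``coverage`` (the >=2-row
    maximal blocks) when given, else against ``candidates`` itself.
    """
    candidates = list(candidates)
    cov = list(coverage) if coverage is not None else candidates
    out = set(candidates)
    out.update(one_row_blocks(msa, cov))
    out.update(one_character_blocks(msa))
    return sorted(out)


def build_window_candidates(
    window_msa: MSA, strategy: Strategy, min_rows: int = 2
) -> list[Block]:
    """Candidate set of one free window: maximal blocks, their decomposition,
    one-row blocks and one-character blocks, deduplicated."""
    maximal = enumerate_maximal_blocks(window_msa, min_rows=min_rows)
    decomposed = decompose_all(window_msa, maximal, strategy)
    return add_short_blocks(window_msa, decomposed, coverage=maximal)


def build_instance(
    msa: MSA,
    alpha: int | None,
    strategy: Strategy = "row-maximal",
    min_rows: int = 2,
) -> BuildResult:
    """Force vertical blocks, split into windows, and build one solver
    instance per free window (enumeration and decomposition run per window)."""
    forced = find_vertical_blocks(msa, alpha)
    windows = split_by_vertical(msa, forced)
    instances: list[MWBCInstance] = []
    for w in windows:
        if w.role != "free":
            continue
        sub = msa.window(w.start, w.end)
        cands = build_window_candidates(sub, strategy, min_rows=min_rows)
        instances.append(
            MWBCInstance(sub, offset=w.start - 1, candidates=tuple(cands), alpha=alpha)
        )
    return BuildResult(instances=instances, forced=forced, windows=windows)


def breakpoints_tsv(msa: MSA) -> str:
    lines = ["alpha\tlongest_subMSA_columns"]
    for a, v in breakpoints(msa):
        lines.append(f"{a}\t{v}")
    return "\n".join(lines) + "\n"
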