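"""Exact-cover ILP for the minimum-weight block cover (MWBC) problem.

One binary variable per candidate block, one equality constraint per MSA
cell: every cell must be covered by exactly one selected block.  Five
objective functions weigh the blocks:

* ``blocks`` — unit cost: minimise the number of blocks;
* ``weighted`` — cost ``Delta`` for blocks whose gap-free label length is at
  most ``q``, else 1: prefer long-labelled nodes;
* ``depth`` — cost ``Delta`` for blocks used by at most ``floor(p * m)``
  rows, else 1: prefer high-coverage nodes;
* ``strings`` — cost = gap-free label length: minimise total graph length;
* ``penalized-strings`` — label length divided by ``|K|``.

The backend is the HiGHS mixed-integer solver via :func:`scipy.optimize.milp`.
An exhaustive depth-first solver over the same candidate set serves as an
independent optimum oracle on tiny instances, and a variant over *all* blocks
of the alignment solves the unrestricted problem (a lower bound for any
restricted candidate set).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Literal

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .blocks import Block, label
from .instance_builder import MWBCInstance
from .msa_io import MSA, msa_slice

ObjectiveName = Literal["blocks", "weighted", "depth", "strings", "penalized-strings"]

OBJECTIVES: tuple[str, ...] = (
    "blocks",
    "weighted",
    "depth",
    "strings",
    "penalized-strings",
)


class SolverError(RuntimeError):
    """The backend failed in a way that signals an instance-construction bug."""


@dataclass(frozen=True)
class ObjectiveSpec:
    """An objective function and its parameters.

    ``q`` is the label-length threshold of ``weighted``; ``p`` the coverage
    fraction of ``depth`` (penalise blocks with ``|K| <= floor(p*m)``);
    ``delta`` the penalty weight (> 1); ``depth_min_count`` switches ``depth``
    to a literal row-count threshold ``|K| <= depth_min_count``.
    """

    name: ObjectiveName = "blocks"
    q: int = 20
    p: float = 0.11
    delta: float = 1000.0
    depth_min_count: int | None = None

    def __post_init__(self) -> None:
        if self.name not in OBJECTIVES:
            raise ValueError(f"unknown objective {self.name!r}")
        if self.delta <= 1 and self.name in ("weighted", "depth") and self.delta != 1:
            raise ValueError("delta must be > 1 (or exactly 1 to disable)")
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if not 0 < self.p <= 1:
            raise ValueError("p must be in (0, 1]")


@dataclass
class Cover:
    """An exact cover: pairwise non-overlapping blocks covering every cell."""

    blocks: tuple[Block, ...]
    objective_value: float
    optimal: bool = True


def block_cost(msa: MSA, block: Block, obj: ObjectiveSpec) -> float:
    """The ILP coefficient of ``block`` under ``obj``."""
    if obj.name == "blocks":
        return 1.0
    gamma = label(msa, block).ungapped_length
    if obj.name == "weighted":
        return obj.delta if gamma <= obj.q else 1.0
    if obj.name == "depth":
        thr = (
            obj.depth_min_count
            if obj.depth_min_count is not None
            else math.floor(obj.p * msa.m)
        )
        return obj.delta if len(block.rows) <= thr else 1.0
    if obj.name == "strings":
        return float(gamma)
    if obj.name == "penalized-strings":
        return gamma / len(block.rows)
    raise ValueError(f"unknown objective {obj.name!r}")


def _cell_index(msa: MSA) -> dict[tuple[int, int], int]:
    return {
        (r, c): (r - 1) * msa.n + (c - 1)
        for r in range(1, msa.m + 1)
        for c in range(1, msa.n + 1)
    }


def verify_exact_cover(msa: MSA, blocks: Iterable[Block]) -> None:
    """Raise unless ``blocks`` covers every cell of ``msa`` exactly once."""
    seen: dict[tuple[int, int], Block] = {}
    for blk in blocks:
        for cell in blk.cells():
            if cell in seen:
                raise SolverError(
                    f"cell {cell} covered by both {seen[cell]} and {blk}"
                )
            seen[cell] = blk
    missing = msa.m * msa.n - len(seen)
    if missing:
        raise SolverError(f"{missing} cells left uncovered")


def solve_ilp(
    instance: MWBCInstance,
    obj: ObjectiveSpec,
    time_limit: float | None = None,
    solver_seed: int = 0,
) -> Cover:
    """Minimise ``obj`` over exact covers drawn from ``instance.candidates``.

    The model is deterministic for a fixed candidate ordering (candidates are
    kept sorted); ``solver_seed`` is accepted for interface stability but the
    HiGHS backend is already deterministic in single-threaded operation.
    Returns the incumbent flagged non-optimal when the time limit is hit.
    """
    msa = instance.msa
    cands = sorted(instance.candidates)
    if not cands:
        raise SolverError("empty candidate set")
    idx = _cell_index(msa)
    rows_ij: list[int] = []
    cols_ij: list[int] = []
    for j, blk in enumerate(cands):
        for cell in blk.cells():
            rows_ij.append(idx[cell])
            cols_ij.append(j)
    n_cells = msa.m * msa.n
    a_mat = sparse.csc_matrix(
        (np.ones(len(rows_ij)), (rows_ij, cols_ij)), shape=(n_cells, len(cands))
    )
    costs = np.array([block_cost(msa, blk, obj) for blk in cands])
    options = {}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(
        c=costs,
        constraints=LinearConstraint(a_mat, 1.0, 1.0),
        integrality=np.ones(len(cands)),
        bounds=Bounds(0.0, 1.0),
        options=options,
    )
    if res.status == 2:
        raise SolverError(
            "solver reported infeasible: the instance lacks its guaranteed "
            "one-character-block cover (construction bug)"
        )
    if res.x is None:
        raise SolverError(f"solver failed: {res.message}")
    chosen = tuple(blk for j, blk in enumerate(cands) if res.x[j] > 0.5)
    verify_exact_cover(msa, chosen)
    value = float(sum(block_cost(msa, blk, obj) for blk in chosen))
    if res.status == 0 and abs(value - res.fun) > 1e-6 * max(1.0, abs(value)):
        raise SolverError(
            f"objective mismatch: recomputed {value}, solver reported {res.fun}"
        )
    return Cover(chosen, value, optimal=(res.status == 0))


def _exhaustive_min_cover(
    msa: MSA, candidates: list[Block], obj: ObjectiveSpec, max_cells: int
) -> Cover:
    n_cells = msa.m * msa.n
    if n_cells > max_cells:
        raise ValueError(f"instance too large for exhaustive search ({n_cells} cells)")
    idx = _cell_index(msa)
    masks = []
    costs = []
    for blk in sorted(candidates):
        mask = 0
        for cell in blk.cells():
            mask |= 1 << idx[cell]
        masks.append(mask)
        costs.append(block_cost(msa, blk, obj))
    by_cell: list[list[int]] = [[] for _ in range(n_cells)]
    for j, mask in enumerate(masks):
        low = (mask & -mask).bit_length() - 1
        by_cell[low].append(j)
    full = (1 << n_cells) - 1
    cand_sorted = sorted(candidates)

    @lru_cache(maxsize=None)
    def best(covered: int) -> tuple[float, tuple[int, ...]]:
        if covered == full:
            return 0.0, ()
        rem = ~covered & full
        cell = (rem & -rem).bit_length() - 1
        best_cost = math.inf
        best_sel: tuple[int, ...] | None = None
        for j in by_cell[cell]:
            if masks[j] & covered:
                continue
            sub_cost, sub_sel = best(covered | masks[j])
            total = costs[j] + sub_cost
            if total < best_cost - 1e-12:
                best_cost = total
                best_sel = (j,) + sub_sel
        if best_sel is None:
            return math.inf, ()
        return best_cost, best_sel

    value, sel = best(0)
    best.cache_clear()
    if math.isinf(value):
        raise SolverError("no exact cover exists in the candidate set")
    chosen = tuple(cand_sorted[j] for j in sel)
    verify_exact_cover(msa, chosen)
    return Cover(chosen, float(value), optimal=True)


def solve_exhaustive(instance: MWBCInstance, obj: ObjectiveSpec) -> Cover:
    """Exact minimum over all exact covers from the instance's candidates, by
    depth-first search with memoisation.  Guarded to ``m*n <= 30`` cells."""
    return _exhaustive_min_cover(
        instance.msa, list(instance.candidates), obj, max_cells=30
    )


def all_blocks(msa: MSA) -> list[Block]:
    """Every block of the MSA: for each interval, every nonempty subset of
    each class of rows spelling the same string.  Exponential; tiny use only."""
    out: list[Block] = []
    for b in range(1, msa.n + 1):
        for e in range(b, msa.n + 1):
            groups: dict[str, list[int]] = {}
            for r in range(1, msa.m + 1):
                groups.setdefault(msa_slice(msa, r, b, e), []).append(r)
            for rows in groups.values():
                k = len(rows)
                for subset in range(1, 1 << k):
                    sel = tuple(rows[i] for i in range(k) if subset >> i & 1)
                    out.append(Block(b, e, sel))
    return sorted(set(out))


def solve_gmwbc_oracle(msa: MSA, obj: ObjectiveSpec) -> Cover:
    """Global optimum over *all* blocks of the MSA (the unrestricted problem);
    by definition a lower bound for any restricted candidate set.
    Guarded to ``m*n <= 20`` cells."""
    if msa.m * msa.n > 20:
        raise ValueError("instance too large for the unrestricted oracle")
    return _exhaustive_min_cover(msa, all_blocks(msa), obj, max_cells=20)


def shift_cover(cover: Cover, offset: int) -> Cover:
    """Translate a window-local cover back to global column coordinates."""
    return Cover(
        tuple(Block(b.b + offset, b.e + offset, b.rows) for b in cover.blocks),
        cover.objective_value,
        cover.optimal,
    )
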