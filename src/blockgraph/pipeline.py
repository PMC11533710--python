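"""End-to-end orchestration: MSA -> instances -> covers -> variation graph."""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

from .graph_builder import VariationGraph, build_graph, check_lossless, postprocess
from .instance_builder import BuildResult, build_instance
from .msa_io import MSA
from .mwbc_solver import Cover, ObjectiveSpec, shift_cover, solve_ilp


@dataclass
class SolveReport:
    """Per-window solver summary."""

    window_start: int
    window_end: int
    n_candidates: int
    objective_value: float
    n_blocks: int
    optimal: bool


@dataclass
class PipelineResult:
    cover: Cover
    graph_raw: VariationGraph
    graph: VariationGraph
    build: BuildResult
    reports: list[SolveReport] = field(default_factory=list)


def solve_cover(
    msa: MSA,
    objective: ObjectiveSpec,
    alpha: int | None = None,
    strategy: str = "row-maximal",
    min_rows: int = 2,
    time_limit: float | None = None,
    solver_seed: int = 0,
    workers: int = 1,
    prebuilt: BuildResult | None = None,
) -> tuple[Cover, BuildResult, list[SolveReport]]:
    """Global exact cover: forced vertical blocks plus per-window ILP optima.

    Windows are independent; with ``workers > 1`` they are solved in a thread
    pool, and results are assembled in window order so the output is
    identical to sequential execution.  The reported objective value sums the
    window optima plus the cost of the forced blocks.  ``prebuilt`` reuses an
    existing :func:`build_instance` result (instance construction does not
    depend on the objective).
    """
    from .mwbc_solver import block_cost  # local to avoid cycle at import time

    build = prebuilt or build_instance(msa, alpha, strategy, min_rows=min_rows)

    def _solve(inst):
        return solve_ilp(inst, objective, time_limit=time_limit, solver_seed=solver_seed)

    if workers > 1 and len(build.instances) > 1:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            covers = list(pool.map(_solve, build.instances))
    else:
        covers = [_solve(inst) for inst in build.instances]

    blocks = list(build.forced)
    value = sum(block_cost(msa, blk, objective) for blk in build.forced)
    reports: list[SolveReport] = []
    for inst, cov in zip(build.instances, covers):
        shifted = shift_cover(cov, inst.offset)
        blocks.extend(shifted.blocks)
        value += cov.objective_value
        reports.append(
            SolveReport(
                window_start=inst.offset + 1,
                window_end=inst.offset + inst.msa.n,
                n_candidates=len(inst.candidates),
                objective_value=cov.objective_value,
                n_blocks=len(cov.blocks),
                optimal=cov.optimal,
            )
        )
    optimal = all(r.optimal for r in reports)
    return Cover(tuple(sorted(blocks)), float(value), optimal), build, reports


def run_pipeline(
    msa: MSA,
    objective: ObjectiveSpec | None = None,
    alpha: int | None = None,
    strategy: str = "row-maximal",
    min_rows: int = 2,
    time_limit: float | None = None,
    solver_seed: int = 0,
    workers: int = 1,
) -> PipelineResult:
    """Full pipeline; the returned graphs are checked lossless and acyclic."""
    objective = objective or ObjectiveSpec()
    cover, build, reports = solve_cover(
        msa,
        objective,
        alpha=alpha,
        strategy=strategy,
        min_rows=min_rows,
        time_limit=time_limit,
        solver_seed=solver_seed,
        workers=workers,
    )
    graph_raw = build_graph(msa, cover)
    check_lossless(msa, graph_raw)
    graph = postprocess(graph_raw)
    check_lossless(msa, graph)
    return PipelineResult(cover, graph_raw, graph, build, reports)
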