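"""Synthetic alignments with planted block structure, plus a fixed worked
example, so every pipeline stage is testable without external data.

The simulator emulates an alignment of closely related genomes (the regime
this tool targets, e.g. viral isolates): a random ancestor is copied to every
row, per-site substitutions and short indels are applied, and gaps are
planted directly as alignment columns — there is no realignment step, so the
ground truth (which segments are shared by which rows) is exact by
construction.  Designated shared segments are kept mutation-free in all
rows and therefore surface as vertical runs / maximal blocks downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa_io import GAP, MSA, validate_alignment

_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the planted-block MSA simulator.

    Defaults model a small panel of near-identical genomes: 10 rows, a 200 bp
    ancestor, 1% per-site substitutions and 0.5% indel events of up to 3 bp.
    ``shared_segments`` lists ancestor-coordinate intervals (1-based, closed)
    kept mutation-free in every row.
    """

    m: int = 10
    core_length: int = 200
    substitution_rate: float = 0.01
    indel_rate: float = 0.005
    indel_max_len: int = 3
    shared_segments: tuple[tuple[int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2 or self.core_length < 1:
            raise ValueError("need m >= 2 and core_length >= 1")
        for rate in (self.substitution_rate, self.indel_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must be in [0, 1]")


def running_example() -> MSA:
    """The fixed 5x9 worked example used throughout the documentation.

    Five short sequences (AACCGA, AAACGAT, GAACGAT, CAACGAT, AATCCGGAA)
    aligned so that rows 1, 2 and 5 share ``AA`` on columns [1, 2], rows
    2-4 share the label of columns [2, 9], and all five rows share ``GA``
    on columns [7, 8] (a vertical run).
    """
    rows = (
        "AA--CCGA-",
        "AA-AC-GAT",
        "GA-AC-GAT",
        "CA-AC-GAT",
        "AATCCGGAA",
    )
    ids = tuple(f"s{i}" for i in range(1, 6))
    return validate_alignment(MSA(ids, rows), strict=True)


def _in_shared(pos: int, segments: tuple[tuple[int, int], ...]) -> bool:
    return any(b <= pos <= e for b, e in segments)


def simulate_msa(params: SimulationParams) -> MSA:
    """Draw a planted-block MSA; identical params+seed give identical output.

    Columns are materialised ancestor-position by ancestor-position: inserted
    segments become columns where only the inserting row has bases, deleted
    positions become gaps in the deleting row.  If every row deletes the same
    position the all-gap column is dropped; if that empties the alignment the
    draw is retried with a derived seed (bounded retries).
    """
    for attempt in range(20):
        rng = np.random.default_rng((params.seed + attempt * 2_000_003) % 2**31)
        msa = _simulate_once(params, rng)
        if msa is not None:
            return msa
    raise RuntimeError("simulation failed to produce a valid MSA; relax the rates")


def _simulate_once(params: SimulationParams, rng: np.random.Generator) -> MSA | None:
    L = params.core_length
    ancestor = "".join(rng.choice(list(_BASES), size=L))
    # per row: mutated copy plus per-boundary insertions
    row_chars: list[list[str]] = []
    row_ins: list[dict[int, str]] = []  # insertions after ancestor position j
    for _ in range(params.m):
        chars = list(ancestor)
        ins: dict[int, str] = {}
        j = 1
        while j <= L:
            if not _in_shared(j, params.shared_segments):
                u = rng.random()
                if u < params.substitution_rate:
                    old = chars[j - 1]
                    chars[j - 1] = rng.choice([b for b in _BASES if b != old])
                elif u < params.substitution_rate + params.indel_rate:
                    length = int(rng.integers(1, params.indel_max_len + 1))
                    if rng.random() < 0.5:  # deletion
                        for d in range(length):
                            if j + d <= L and not _in_shared(
                                j + d, params.shared_segments
                            ):
                                chars[j + d - 1] = GAP
                        j += length
                        continue
                    # insertion after position j (never inside a shared segment)
                    ins[j] = "".join(rng.choice(list(_BASES), size=length))
            j += 1
        row_chars.append(chars)
        row_ins.append(ins)
    # materialise columns
    columns: list[str] = []
    for j in range(1, L + 1):
        col = "".join(row_chars[r][j - 1] for r in range(params.m))
        if set(col) != {GAP}:
            columns.append(col)
        for r in range(params.m):
            seg = row_ins[r].get(j)
            if seg:
                for ch in seg:
                    columns.append(
                        GAP * r + ch + GAP * (params.m - r - 1)
                    )
    if not columns:
        return None
    rows = tuple(
        "".join(col[r] for col in columns) for r in range(params.m)
    )
    if any(set(row) == {GAP} for row in rows):
        return None
    ids = tuple(f"g{r+1}" for r in range(params.m))
    return validate_alignment(MSA(ids, rows), strict=True)


def random_msa(
    seed: int,
    max_rows: int = 5,
    max_cols: int = 8,
    alphabet: str = "AC-",
) -> MSA:
    """A small uniformly random valid MSA for property-test batteries.

    Columns are drawn i.i.d. over ``alphabet`` and redrawn while all-gap;
    rows that end up all-gap get one random base planted.
    """
    rng = np.random.default_rng(seed % 2**31)
    m = int(rng.integers(2, max_rows + 1))
    n = int(rng.integers(1, max_cols + 1))
    cols: list[str] = []
    for _ in range(n):
        while True:
            col = "".join(rng.choice(list(alphabet), size=m))
            if set(col) != {GAP}:
                cols.append(col)
                break
    rows = ["".join(col[r] for col in cols) for r in range(m)]
    bases = [ch for ch in alphabet if ch != GAP]
    for r in range(m):
        if set(rows[r]) == {GAP}:
            j = int(rng.integers(0, n))
            rows[r] = rows[r][:j] + str(rng.choice(bases)) + rows[r][j + 1 :]
    ids = tuple(f"r{r+1}" for r in range(m))
    return validate_alignment(MSA(ids, tuple(rows)), strict=True)
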