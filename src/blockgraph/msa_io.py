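"""Reading, validating and indexing multiple sequence alignments.

An MSA here is a rectangular character matrix over the DNA alphabet
``{A, C, G, T, N}`` extended with the gap (indel) symbol ``-``.  Every row is
the gapped expansion of one input sequence.  Validity requires that no column
consists of gaps only and (in strict mode) that no row is gaps only.

All coordinates exposed by this package are **1-based with closed intervals**
``[b, e]``, matching the standard notation for alignment columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Characters an MSA row may contain after normalisation.
ALPHABET = frozenset("ACGTN-")

GAP = "-"


class MSAError(ValueError):
    """Malformed multiple sequence alignment."""


@dataclass(frozen=True)
class MSA:
    """An in-memory multiple sequence alignment.

    Parameters
    ----------
    row_ids:
        One identifier per row, in file order.  Duplicates are allowed; rows
        are addressed by their 1-based index.
    rows:
        The gapped row strings, all of equal length.
    """

    row_ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rows) == 0:
            raise MSAError("empty MSA: at least one row is required")
        if len(self.row_ids) != len(self.rows):
            raise MSAError("row_ids and rows must have equal length")
        n = len(self.rows[0])
        if n == 0:
            raise MSAError("MSA rows must be nonempty")
        for i, row in enumerate(self.rows, start=1):
            if len(row) != n:
                raise MSAError(
                    f"length mismatch: row {i} has length {len(row)}, expected {n}"
                )
            bad = set(row) - ALPHABET
            if bad:
                raise MSAError(
                    f"row {i} contains characters outside the alphabet: {sorted(bad)}"
                )

    @property
    def m(self) -> int:
        """Number of rows."""
        return len(self.rows)

    @property
    def n(self) -> int:
        """Alignment length (number of columns)."""
        return len(self.rows[0])

    def column(self, j: int) -> str:
        """The characters of column ``j`` (1-based), top to bottom."""
        if not 1 <= j <= self.n:
            raise IndexError(f"column {j} out of range [1, {self.n}]")
        return "".join(row[j - 1] for row in self.rows)

    def window(self, b: int, e: int) -> "MSA":
        """Column-window sub-alignment over the closed interval ``[b, e]``.

        The window keeps every row (a row may become gaps-only; that is legal
        for internal sub-alignments, which are never re-validated strictly).
        """
        if not 1 <= b <= e <= self.n:
            raise IndexError(f"window [{b}, {e}] out of range [1, {self.n}]")
        return MSA(self.row_ids, tuple(row[b - 1 : e] for row in self.rows))


def _normalise(seq: str, record_id: str, strict: bool) -> str:
    s = seq.upper().replace(".", GAP)
    bad = set(s) - ALPHABET
    if bad:
        if strict:
            raise MSAError(
                f"record {record_id!r} contains characters outside "
                f"{{A,C,G,T,N,-}}: {sorted(bad)}"
            )
        logger.warning(
            "record %r: mapping %s to N", record_id, sorted(bad)
        )
        for ch in bad:
            s = s.replace(ch, "N")
    return s


def validate_alignment(msa: MSA, strict: bool = True) -> MSA:
    """Check the Def-3-style constraints: no gap-only column, no gap-only row.

    In strict mode violations raise :class:`MSAError`; otherwise gap-only
    columns are dropped with a warning (a gap-only row always raises, since
    dropping it would renumber the remaining rows).
    """
    gap_cols = [
        j for j in range(1, msa.n + 1) if set(msa.column(j)) == {GAP}
    ]
    if gap_cols:
        if strict:
            raise MSAError(
                f"degenerate columns (gaps only): {gap_cols}"
            )
        logger.warning("dropping %d gap-only columns: %s", len(gap_cols), gap_cols)
        keep = [j for j in range(1, msa.n + 1) if j not in set(gap_cols)]
        if not keep:
            raise MSAError("all columns are gaps only")
        msa = MSA(
            msa.row_ids,
            tuple("".join(row[j - 1] for j in keep) for row in msa.rows),
        )
    for i, row in enumerate(msa.rows, start=1):
        if set(row) == {GAP}:
            raise MSAError(f"row {i} ({msa.row_ids[i-1]!r}) contains only gaps")
    return msa


def read_msa(path: str | Path, strict: bool = True) -> MSA:
    """Read an aligned FASTA file into an :class:`MSA`.

    All records must have equal length.  Characters are uppercased, ``.`` is
    accepted as a gap synonym.  In non-strict mode, characters outside the
    alphabet are mapped to ``N`` and gap-only columns are dropped, both with a
    logged warning; in strict mode either condition is an error.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise MSAError(f"no FASTA records found in {path}")
    ids = tuple(r.id for r in records)
    rows = tuple(_normalise(str(r.seq), r.id, strict) for r in records)
    return validate_alignment(MSA(ids, rows), strict=strict)


def write_msa(msa: MSA, path: str | Path) -> None:
    """Write an :class:`MSA` as aligned FASTA (inverse of :func:`read_msa`)."""
    records = [
        SeqRecord(Seq(row), id=rid, description="")
        for rid, row in zip(msa.row_ids, msa.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def ungapped(msa: MSA, row: int) -> str:
    """The input sequence of ``row`` (1-based): the row with gaps removed."""
    if not 1 <= row <= msa.m:
        raise IndexError(f"row {row} out of range [1, {msa.m}]")
    return msa.rows[row - 1].replace(GAP, "")


def msa_slice(msa: MSA, row: int, b: int, e: int) -> str:
    """Gapped substring of ``row`` over the closed column interval ``[b, e]``."""
    if not 1 <= row <= msa.m:
        raise IndexError(f"row {row} out of range [1, {msa.m}]")
    if not 1 <= b <= e <= msa.n:
        raise IndexError(f"interval [{b}, {e}] out of range [1, {msa.n}]")
    return msa.rows[row - 1][b - 1 : e]
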