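"""Conservation analysis of a provided multiple sequence alignment.

Rows with more than a maximum gap fraction (default 25%) are removed, then
per-column residue frequencies are computed and mapped to the numbering of a
designated reference sequence.  Conservation of a residue at a reference
position is the percentage of gap-free rows carrying that residue at the
column (gaps are excluded from numerator and denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import AlignIO

from .geometry import ValidationError

__all__ = [
    "AMINO_ACIDS",
    "Alignment",
    "conservation",
    "filter_gappy",
    "frequency_logo_table",
    "load_alignment",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


@dataclass
class Alignment:
    """Equal-length gapped rows with ids, plus a reference for numbering.

    ``ref_start`` is the residue number of the reference's first non-gap
    column (e.g. 130 for an alignment of the 130-310 region).
    """

    rows: list[tuple[str, str]]
    reference_id: str
    ref_start: int = 1
    _colmap: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValidationError("alignment has no rows")
        length = len(self.rows[0][1])
        for rid, seq in self.rows:
            if len(seq) != length:
                raise ValidationError(f"row {rid} length differs from the alignment")
        ref = self.reference_row()
        # reference numbering: consecutive over the reference's non-gap columns
        self._colmap = {}
        pos = self.ref_start
        for col, ch in enumerate(ref):
            if ch != GAP:
                self._colmap[pos] = col
                pos += 1

    def reference_row(self) -> str:
        for rid, seq in self.rows:
            if rid == self.reference_id:
                return seq
        raise ValidationError(f"reference {self.reference_id!r} not in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    def column_of(self, position: int) -> int:
        """Alignment column index of a reference residue number."""
        try:
            return self._colmap[position]
        except KeyError:
            raise ValidationError(
                f"position {position} outside the aligned reference region"
            ) from None

    def positions(self) -> list[int]:
        return sorted(self._colmap)


def load_alignment(path: str | Path, reference_id: str, ref_start: int = 1) -> Alignment:
    """Read a gapped FASTA alignment."""
    records = AlignIO.read(str(path), "fasta")
    rows = [(rec.id, str(rec.seq).upper()) for rec in records]
    return Alignment(rows=rows, reference_id=reference_id, ref_start=ref_start)


def gap_fraction(seq: str) -> float:
    return seq.count(GAP) / len(seq)


def filter_gappy(alignment: Alignment, max_gap_fraction: float = 0.25) -> Alignment:
    """Drop rows whose gap fraction strictly exceeds the threshold.

    The reference row is never removed; a reference exceeding the threshold
    is an error since numbering cannot proceed without it.
    """
    if gap_fraction(alignment.reference_row()) > max_gap_fraction:
        raise ValidationError("reference sequence exceeds the gap threshold")
    kept = [
        (rid, seq)
        for rid, seq in alignment.rows
        if rid == alignment.reference_id or gap_fraction(seq) <= max_gap_fraction
    ]
    return Alignment(rows=kept, reference_id=alignment.reference_id, ref_start=alignment.ref_start)


def conservation(alignment: Alignment, position: int, residue: str) -> float:
    """Percent of gap-free rows carrying ``residue`` at a reference position."""
    col = alignment.column_of(position)
    chars = [seq[col] for _rid, seq in alignment.rows if seq[col] != GAP]
    if not chars:
        return 0.0
    return 100.0 * sum(1 for c in chars if c == residue.upper()) / len(chars)


def frequency_logo_table(alignment: Alignment) -> pd.DataFrame:
    """Per-reference-position residue frequencies (percent, over all rows).

    One row per reference position with the 20 amino-acid frequencies plus
    the gap fraction; each row sums to 100% over residues + gap.  (This is
    the table underlying a sequence-logo rendering.)
    """
    n = len(alignment.rows)
    records = []
    for pos in alignment.positions():
        col = alignment.column_of(pos)
        counts: dict[str, int] = {}
        for _rid, seq in alignment.rows:
            counts[seq[col]] = counts.get(seq[col], 0) + 1
        row: dict[str, object] = {"position": pos}
        for aa in AMINO_ACIDS:
            row[aa] = 100.0 * counts.get(aa, 0) / n
        other = sum(v for k, v in counts.items() if k not in AMINO_ACIDS and k != GAP)
        row["other"] = 100.0 * other / n
        row["gap"] = 100.0 * counts.get(GAP, 0) / n
        records.append(row)
    return pd.DataFrame(records)
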