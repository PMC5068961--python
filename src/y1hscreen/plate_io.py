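"""Reading, writing and structuring arrayed colony-quantification data.

A yeast one-hybrid (Y1H) selection plate carries 1536 colony positions on a
32 x 48 grid.  Each transformant genotype (one DNA bait paired with one
activation-domain-fused transcription factor, or a negative control) is
spotted four times in a quartet of neighbouring wells, so the plate holds a
16 x 24 grid of quartets mirroring the 384-position source array.

This module parses colony quantification tables in the tab-separated dialect
produced by colony-scoring tools such as Gitter (row, column, pixel area,
circularity, flags), holds plate-level metadata, and groups colonies into
quartets carrying the natural-log areas of their present, circular colonies.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, TextIO, Union

__all__ = [
    "GRID_ROWS",
    "GRID_COLS",
    "QUARTET_ROWS",
    "QUARTET_COLS",
    "Control",
    "ColonyRecord",
    "PlateMeta",
    "ArrayMap",
    "Quartet",
    "GitterDialect",
    "GitterParseError",
    "DuplicatePositionError",
    "DialectConfigError",
    "read_gitter_table",
    "write_gitter_table",
    "read_well_mask",
    "assemble_quartets",
    "well_to_quartet",
]

GRID_ROWS = 32
GRID_COLS = 48
QUARTET_ROWS = 16
QUARTET_COLS = 24

VALID_3AT_LEVELS = (0, 10, 20, 40, 60, 80, 100)
VALID_DAYS = (3, 7, 10)


class GitterParseError(ValueError):
    """A data line could not be parsed (message carries the line number)."""


class DuplicatePositionError(ValueError):
    """Two records claim the same (row, col) position."""


class DialectConfigError(ValueError):
    """The column-mapping config names a column absent from the table."""


class Control(str, Enum):
    """Negative-control occupants of array positions.

    ``EMPTY_NO_TF`` marks cells never transformed with any TF construct;
    ``AD_ONLY`` marks cells carrying the bare activation domain.  Both report
    background reporter activation and are never called as interactions.
    """

    EMPTY_NO_TF = "empty_no_tf"
    AD_ONLY = "ad_only"


Occupant = Union[str, Control]


@dataclass(frozen=True)
class ColonyRecord:
    """One detected (or absent) colony at a 1536-grid position."""

    well_row: int
    well_col: int
    pixel_area: int
    circular: bool = True
    present: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.well_row <= GRID_ROWS):
            raise ValueError(f"well_row {self.well_row} outside 1..{GRID_ROWS}")
        if not (1 <= self.well_col <= GRID_COLS):
            raise ValueError(f"well_col {self.well_col} outside 1..{GRID_COLS}")
        if self.pixel_area < 0:
            raise ValueError("pixel_area must be non-negative")
        if not self.present and self.pixel_area != 0:
            raise ValueError("absent colony must have pixel_area 0")


@dataclass(frozen=True)
class PlateMeta:
    """Identity and screening conditions of one 1536-position plate."""

    plate_id: str
    bait_id: str
    species: str  # "mel", "pse" or "will"
    selection_3at_mM: int
    day: int
    tf_array_id: str
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.selection_3at_mM not in VALID_3AT_LEVELS:
            raise ValueError(
                f"3AT level {self.selection_3at_mM} not in {VALID_3AT_LEVELS}"
            )
        if self.day not in VALID_DAYS:
            raise ValueError(f"day {self.day} not in {VALID_DAYS}")
        if self.day == 3 and self.selection_3at_mM != 0:
            raise ValueError("day-3 imaging applies only to the permissive (0 mM) plate")
        if self.species not in ("mel", "pse", "will"):
            raise ValueError(f"unknown species {self.species!r}")


class ArrayMap:
    """Occupant assignment for every quartet position of one TF source array.

    Maps (qrow, qcol) with qrow in 1..16 and qcol in 1..24 to either a TF
    identifier (string) or a :class:`Control`.  Every position must be
    assigned exactly once.
    """

    def __init__(self, array_id: str, assignments: Mapping[tuple[int, int], Occupant]):
        expected = {
            (r, c)
            for r in range(1, QUARTET_ROWS + 1)
            for c in range(1, QUARTET_COLS + 1)
        }
        got = set(assignments)
        if got != expected:
            missing = expected - got
            extra = got - expected
            raise ValueError(
                f"array map must cover the {QUARTET_ROWS}x{QUARTET_COLS} quartet grid "
                f"exactly once ({len(missing)} missing, {len(extra)} out of range)"
            )
        self.array_id = array_id
        self._assignments = dict(assignments)

    def __getitem__(self, pos: tuple[int, int]) -> Occupant:
        return self._assignments[pos]

    def occupant(self, qrow: int, qcol: int) -> Occupant:
        return self._assignments[(qrow, qcol)]

    def items(self):
        return self._assignments.items()

    @property
    def tf_ids(self) -> list[str]:
        return sorted(
            {o for o in self._assignments.values() if not isinstance(o, Control)}
        )

    @classmethod
    def from_tf_list(
        cls,
        array_id: str,
        tf_ids: Iterable[str],
        n_ad_only: int = 8,
    ) -> "ArrayMap":
        """Fill the quartet grid row-major with TFs, then AD-only controls,
        then empty positions.  Raises if more TFs than positions."""
        tf_ids = list(tf_ids)
        n_positions = QUARTET_ROWS * QUARTET_COLS
        if len(tf_ids) > n_positions:
            raise ValueError(f"{len(tf_ids)} TFs exceed {n_positions} array positions")
        occupants: list[Occupant] = list(tf_ids)
        n_free = n_positions - len(tf_ids)
        occupants += [Control.AD_ONLY] * min(n_ad_only, n_free)
        occupants += [Control.EMPTY_NO_TF] * (n_positions - len(occupants))
        assignments = {}
        k = 0
        for r in range(1, QUARTET_ROWS + 1):
            for c in range(1, QUARTET_COLS + 1):
                assignments[(r, c)] = occupants[k]
                k += 1
        return cls(array_id, assignments)


@dataclass
class Quartet:
    """The 4-replicate spot group for one bait/occupant combination.

    ``ln_areas`` holds the natural-log pixel areas of the quartet's present,
    circular colonies only (absent or noncircular spots contribute nothing).
    """

    bait_id: str
    occupant: Occupant
    qrow: int
    qcol: int
    ln_areas: list[float] = field(default_factory=list)
    n_positions: int = 4

    @property
    def n_present_circular(self) -> int:
        return len(self.ln_areas)


@dataclass(frozen=True)
class GitterDialect:
    """Column mapping and noncircularity convention for a Gitter-style table.

    A colony is noncircular when its flag field contains ``noncircular_flag``
    or, if ``circularity_cutoff`` is set, when its circularity value falls
    below the cutoff.  The default relies on the flag alone.
    """

    row_col: str = "row"
    col_col: str = "col"
    size_col: str = "size"
    circularity_col: str = "circularity"
    flags_col: str = "flags"
    noncircular_flag: str = "NC"
    circularity_cutoff: float | None = None


DEFAULT_DIALECT = GitterDialect()

_NA_FLAGS = ("", "-", "NA")


def _open_source(source) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8")
    if isinstance(source, bytes):
        return io.StringIO(source.decode("utf-8"))
    return source


def read_gitter_table(source, dialect: GitterDialect = DEFAULT_DIALECT) -> list[ColonyRecord]:
    """Parse a tab-separated colony table into :class:`ColonyRecord` objects.

    Lines starting with ``#`` are comments.  The first non-comment line is
    the header; ``dialect`` names the row/column/size/circularity/flag
    columns.  A pixel area of 0 is recorded as an absent colony
    (``present=False``), never as a zero-area colony.
    """
    fh = _open_source(source)
    close = isinstance(source, (str, Path, bytes))
    try:
        header: list[str] | None = None
        records: list[ColonyRecord] = []
        seen: set[tuple[int, int]] = set()
        idx: dict[str, int] = {}
        circ_idx: int | None = None
        flags_idx: int | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                for name, col in (
                    ("row", dialect.row_col),
                    ("col", dialect.col_col),
                    ("size", dialect.size_col),
                ):
                    if col not in header:
                        raise DialectConfigError(
                            f"dialect names {name} column {col!r}, absent from header {header}"
                        )
                    idx[name] = header.index(col)
                circ_idx = (
                    header.index(dialect.circularity_col)
                    if dialect.circularity_col in header
                    else None
                )
                if dialect.circularity_cutoff is not None and circ_idx is None:
                    raise DialectConfigError(
                        f"circularity cutoff set but column {dialect.circularity_col!r} missing"
                    )
                flags_idx = (
                    header.index(dialect.flags_col)
                    if dialect.flags_col in header
                    else None
                )
                continue
            if len(fields) < len(header):
                raise GitterParseError(
                    f"line {lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            try:
                row = int(fields[idx["row"]])
                col = int(fields[idx["col"]])
                size = int(float(fields[idx["size"]]))
            except ValueError as exc:
                raise GitterParseError(f"line {lineno}: {exc}") from None
            if not (1 <= row <= GRID_ROWS and 1 <= col <= GRID_COLS):
                raise GitterParseError(
                    f"line {lineno}: position ({row},{col}) outside the "
                    f"{GRID_ROWS}x{GRID_COLS} grid"
                )
            if (row, col) in seen:
                raise DuplicatePositionError(
                    f"line {lineno}: duplicate position ({row},{col})"
                )
            seen.add((row, col))
            circular = True
            if flags_idx is not None:
                flags = fields[flags_idx].strip()
                if flags not in _NA_FLAGS and dialect.noncircular_flag in flags.split(","):
                    circular = False
            if circular and dialect.circularity_cutoff is not None:
                circ_raw = fields[circ_idx].strip()
                if circ_raw not in _NA_FLAGS:
                    try:
                        if float(circ_raw) < dialect.circularity_cutoff:
                            circular = False
                    except ValueError as exc:
                        raise GitterParseError(f"line {lineno}: {exc}") from None
            present = size > 0
            records.append(
                ColonyRecord(
                    well_row=row,
                    well_col=col,
                    pixel_area=size if present else 0,
                    circular=circular,
                    present=present,
                )
            )
        return records
    finally:
        if close:
            fh.close()


def write_gitter_table(
    records: Iterable[ColonyRecord],
    sink,
    dialect: GitterDialect = DEFAULT_DIALECT,
) -> None:
    """Emit records as a tab-separated table re-readable by
    :func:`read_gitter_table` with the same dialect."""
    fh = sink if hasattr(sink, "write") else open(sink, "w", encoding="utf-8")
    close = not hasattr(sink, "write")
    try:
        header = [
            dialect.row_col,
            dialect.col_col,
            dialect.size_col,
            dialect.circularity_col,
            dialect.flags_col,
        ]
        fh.write("\t".join(header) + "\n")
        for rec in records:
            flags = dialect.noncircular_flag if not rec.circular else "-"
            circ = "1.00" if rec.circular else "0.00"
            fh.write(
                f"{rec.well_row}\t{rec.well_col}\t{rec.pixel_area}\t{circ}\t{flags}\n"
            )
    finally:
        if close:
            fh.close()


def read_well_mask(source) -> dict[str, set[tuple[int, int]]]:
    """Read a well-mask TSV (plate_id, well_row, well_col).

    Masked wells are forced to ``present=False`` during quartet assembly;
    this reproduces upstream manual removal of contaminant colonies as data
    rather than code.
    """
    fh = _open_source(source)
    close = isinstance(source, (str, Path, bytes))
    try:
        mask: dict[str, set[tuple[int, int]]] = {}
        header_skipped = False
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if not header_skipped:
                header_skipped = True
                if not parts[1].strip().isdigit():
                    continue
            plate_id, row, col = parts[0], int(parts[1]), int(parts[2])
            mask.setdefault(plate_id, set()).add((row, col))
        return mask
    finally:
        if close:
            fh.close()


def well_to_quartet(well_row: int, well_col: int) -> tuple[int, int]:
    """Map a 1536-grid well to its owning quartet on the 16 x 24 grid.

    Quartet (qrow, qcol) owns wells (2*qrow-1..2*qrow, 2*qcol-1..2*qcol) —
    the standard 384-to-1536 quadruplication geometry.
    """
    return (well_row + 1) // 2, (well_col + 1) // 2


def assemble_quartets(
    records: Iterable[ColonyRecord],
    meta: PlateMeta,
    array: ArrayMap,
    mask: set[tuple[int, int]] | None = None,
) -> list[Quartet]:
    """Group one plate's colony records into 384 quartets.

    Wells missing from ``records`` are treated as absent colonies.  Only
    present, circular colonies with pixel_area > 0 contribute an ln-area.
    """
    by_pos: dict[tuple[int, int], ColonyRecord] = {}
    for rec in records:
        pos = (rec.well_row, rec.well_col)
        if pos in by_pos:
            raise DuplicatePositionError(f"duplicate well {pos}")
        by_pos[pos] = rec
    if len(by_pos) > GRID_ROWS * GRID_COLS:
        raise ValueError("more records than grid positions")  # pragma: no cover
    mask = mask or set()
    quartets: list[Quartet] = []
    for qrow in range(1, QUARTET_ROWS + 1):
        for qcol in range(1, QUARTET_COLS + 1):
            ln_areas: list[float] = []
            for wr in (2 * qrow - 1, 2 * qrow):
                for wc in (2 * qcol - 1, 2 * qcol):
                    rec = by_pos.get((wr, wc))
                    if rec is None or (wr, wc) in mask:
                        continue
                    if rec.present and rec.circular and rec.pixel_area > 0:
                        ln_areas.append(math.log(rec.pixel_area))
            quartets.append(
                Quartet(
                    bait_id=meta.bait_id,
                    occupant=array.occupant(qrow, qcol),
                    qrow=qrow,
                    qcol=qcol,
                    ln_areas=ln_areas,
                )
            )
    return quartets
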