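"""Quartet-level quality control.

Each bait-prey combination is replicated as four neighbouring spots.  Before
any plate-level statistics, every quartet passes through three filters
applied in order to the natural-log areas of its present, circular colonies:

(a) fewer than two detectable circular colonies -> excluded (a single spot
    cannot distinguish growth from a stray colony);
(b) mean ln-area below 2 (about 7 pixels) -> excluded as background-level
    growth;
(c) index of dispersion (sample variance / mean) above 0.2 -> excluded as
    internally inconsistent.

Surviving quartets are summarised by the mean of their ln-areas.  Boundary
values survive: a quartet with mean exactly 2 or dispersion exactly 0.2 is
kept, matching the strict inequalities of the exclusion rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from statistics import fmean, variance
from typing import Iterable, Sequence

from .plate_io import Occupant, Quartet

__all__ = [
    "QuartetStatus",
    "QuartetValue",
    "ln_area",
    "index_of_dispersion",
    "qc_quartet",
    "qc_plate",
    "MIN_COLONIES",
    "MIN_MEAN_LN_AREA",
    "MAX_DISPERSION",
]

MIN_COLONIES = 2
MIN_MEAN_LN_AREA = 2.0
MAX_DISPERSION = 0.2


class QuartetStatus(str, Enum):
    OK = "ok"
    EXCLUDED_SINGLE_COLONY = "excluded_single_colony"
    EXCLUDED_LOW_AREA = "excluded_low_area"
    EXCLUDED_DISPERSION = "excluded_dispersion"


@dataclass(frozen=True)
class QuartetValue:
    """QC verdict and summary value for one quartet.

    ``value`` is the mean ln-area; it is populated for every quartet with at
    least one colony (so excluded quartets remain inspectable) but is only
    meaningful downstream when ``status`` is ``OK``.
    """

    bait_id: str
    occupant: Occupant
    qrow: int
    qcol: int
    value: float
    status: QuartetStatus

    @property
    def ok(self) -> bool:
        return self.status is QuartetStatus.OK


def ln_area(pixel_area: int) -> float:
    """Natural log of a colony's pixel count.

    Raises ``ValueError`` for pixel_area < 1; a zero-pixel position means no
    colony was detected and never reaches this function.
    """
    if pixel_area < 1:
        raise ValueError(f"pixel_area must be >= 1, got {pixel_area}")
    return math.log(pixel_area)


def index_of_dispersion(values: Sequence[float]) -> float:
    """Sample variance (n-1 denominator) divided by the mean.

    Used as a consistency measure across a quartet's replicate spots.
    Requires at least two values and a nonzero mean.
    """
    if len(values) < 2:
        raise ValueError("index of dispersion needs >= 2 values")
    mean = fmean(values)
    if mean == 0:
        raise ZeroDivisionError("index of dispersion undefined for zero mean")
    return variance(values) / mean


def qc_quartet(
    q: Quartet,
    min_colonies: int = MIN_COLONIES,
    min_mean: float = MIN_MEAN_LN_AREA,
    max_dispersion: float = MAX_DISPERSION,
) -> QuartetValue:
    """Apply the quartet filters in order and return one summary value.

    The first failing rule determines the status; rule order is fixed
    (colony count, then mean area, then dispersion).
    """
    ln_areas = q.ln_areas
    if len(ln_areas) < min_colonies:
        status = QuartetStatus.EXCLUDED_SINGLE_COLONY
        value = fmean(ln_areas) if ln_areas else math.nan
    else:
        value = fmean(ln_areas)
        if value < min_mean:
            status = QuartetStatus.EXCLUDED_LOW_AREA
        elif index_of_dispersion(ln_areas) > max_dispersion:
            status = QuartetStatus.EXCLUDED_DISPERSION
        else:
            status = QuartetStatus.OK
    return QuartetValue(
        bait_id=q.bait_id,
        occupant=q.occupant,
        qrow=q.qrow,
        qcol=q.qcol,
        value=value,
        status=status,
    )


def qc_plate(quartets: Iterable[Quartet], **kwargs) -> list[QuartetValue]:
    """Apply :func:`qc_quartet` to every quartet of a plate."""
    return [qc_quartet(q, **kwargs) for q in quartets]
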