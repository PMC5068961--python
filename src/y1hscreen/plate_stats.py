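"""Per-plate background estimation and quartet Z-scores.

Growth above plate background is the readout of a bait-prey interaction, so
each plate's quartet values are referenced to a background distribution
built from that same plate:

1. **Edge correction.**  Colonies in the outermost two quartet rows and
   columns of a plate often grow differently (nutrient and drying
   gradients).  A two-sample t-test (Welch by default) compares the 144
   edge quartets against the 240 interior quartets; when significant at
   ``alpha_edge`` every edge quartet's value is shifted by minus the
   difference of stratum means, equalising them.
2. **Outlier screening.**  An iterative two-sided Grubbs test removes the
   most extreme value while its standardised deviation exceeds the
   Student-t-derived critical value, so that genuine interactions do not
   inflate the background spread.
3. **Scoring.**  The survivors' mean and sample standard deviation define
   the background; every QC-passing quartet — including the ones Grubbs
   removed — receives z = (corrected value - mean)/sd and a one-sided
   upper-tail standard-normal p-value.

The edge shift is applied as a signed correction even when the edge mean is
below the interior mean; downward adjustment is simply the common case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .quartet_qc import QuartetValue

__all__ = [
    "PlateStats",
    "ScoredQuartet",
    "UnscorablePlateError",
    "grubbs_critical_value",
    "grubbs_screen",
    "edge_correction",
    "is_edge_quartet",
    "score_plate",
]

EDGE_ROWS = frozenset({1, 2, 15, 16})
EDGE_COLS = frozenset({1, 2, 23, 24})


class UnscorablePlateError(ValueError):
    """Raised when a plate has too few usable quartets to define background."""


@dataclass(frozen=True)
class PlateStats:
    """Background distribution of one plate after screening and correction."""

    plate_id: str
    edge_effect_detected: bool
    edge_shift: float
    background_mean: float
    background_sd: float
    n_outliers_removed: int
    outlier_alpha: float
    edge_alpha: float


@dataclass(frozen=True)
class ScoredQuartet:
    """A QC-passing quartet with its edge-corrected value, z and p."""

    quartet: QuartetValue
    corrected_value: float
    z: float
    p: float
    is_outlier: bool

    # convenience pass-throughs
    @property
    def bait_id(self) -> str:
        return self.quartet.bait_id

    @property
    def occupant(self):
        return self.quartet.occupant

    @property
    def qrow(self) -> int:
        return self.quartet.qrow

    @property
    def qcol(self) -> int:
        return self.quartet.qcol


def is_edge_quartet(qrow: int, qcol: int) -> bool:
    """Whether a quartet sits in the outermost two rows or columns of the
    16 x 24 quartet grid (144 of the 384 positions)."""
    return qrow in EDGE_ROWS or qcol in EDGE_COLS


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value for sample size ``n``.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2)) with t the upper
    alpha/(2n) quantile of Student's t on n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_screen(
    values, alpha: float = 0.05
) -> tuple[np.ndarray, list[int]]:
    """Iteratively remove two-sided Grubbs outliers.

    At each step the value farthest from the current mean (in sample-sd
    units) is removed if its statistic G = max|x_i - mean|/sd exceeds the
    critical value; iteration stops when no value qualifies or fewer than
    three remain.  Returns the surviving values and the indices (into the
    original input) of the removed ones, in removal order.

    A zero-spread input yields no outliers.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("grubbs_screen needs a 1-D sample of length >= 3")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    keep = np.arange(x.size)
    removed: list[int] = []
    while keep.size >= 3:
        sub = x[keep]
        sd = sub.std(ddof=1)
        if sd == 0.0:
            break
        dev = np.abs(sub - sub.mean())
        i = int(np.argmax(dev))
        g = dev[i] / sd
        if g > grubbs_critical_value(keep.size, alpha):
            removed.append(int(keep[i]))
            keep = np.delete(keep, i)
        else:
            break
    return x[keep], removed


def edge_correction(
    quartets: list[QuartetValue],
    alpha: float = 0.05,
    equal_var: bool = False,
) -> tuple[dict[tuple[int, int], float], bool, float]:
    """Test for and remove a plate edge effect on QC-passing quartet values.

    Returns (corrected values keyed by (qrow, qcol), detected flag, shift),
    where shift = mean(edge) - mean(interior).  When the Welch t-test (or
    pooled, with ``equal_var=True``) is significant at ``alpha``, every edge
    quartet's value has the shift subtracted; otherwise values pass through
    unchanged and the shift is reported as 0.

    With fewer than two usable values in either stratum the test is skipped
    and no correction applied.
    """
    ok = [q for q in quartets if q.ok]
    edge = [q for q in ok if is_edge_quartet(q.qrow, q.qcol)]
    interior = [q for q in ok if not is_edge_quartet(q.qrow, q.qcol)]
    corrected = {(q.qrow, q.qcol): q.value for q in ok}
    if len(edge) < 2 or len(interior) < 2:
        return corrected, False, 0.0
    edge_vals = np.array([q.value for q in edge])
    int_vals = np.array([q.value for q in interior])
    if edge_vals.std(ddof=1) == 0.0 and int_vals.std(ddof=1) == 0.0:
        return corrected, False, 0.0
    _, p = stats.ttest_ind(edge_vals, int_vals, equal_var=equal_var)
    if p >= alpha:
        return corrected, False, 0.0
    shift = float(edge_vals.mean() - int_vals.mean())
    for q in edge:
        corrected[(q.qrow, q.qcol)] = q.value - shift
    return corrected, True, shift


def score_plate(
    quartets: list[QuartetValue],
    plate_id: str = "",
    alpha_outlier: float = 0.05,
    alpha_edge: float = 0.05,
    equal_var_edge: bool = False,
) -> tuple[PlateStats, list[ScoredQuartet]]:
    """Score every QC-passing quartet of one plate against its background.

    Pipeline order: edge correction on ok values, Grubbs screening on the
    corrected values, background mean/sd from the survivors, then z and a
    one-sided upper-tail normal p for *every* ok quartet (Grubbs-removed
    quartets included, flagged ``is_outlier``).  QC-excluded quartets carry
    no score and are absent from the output list.

    Raises :class:`UnscorablePlateError` when fewer than three ok quartets
    exist or the survivor spread is zero.
    """
    ok = [q for q in quartets if q.ok]
    if len(ok) < 3:
        raise UnscorablePlateError(
            f"plate {plate_id!r}: only {len(ok)} QC-passing quartets"
        )
    corrected, detected, shift = edge_correction(ok, alpha=alpha_edge, equal_var=equal_var_edge)
    values = np.array([corrected[(q.qrow, q.qcol)] for q in ok])
    survivors, outlier_idx = grubbs_screen(values, alpha=alpha_outlier)
    if survivors.size < 2 or survivors.std(ddof=1) == 0.0:
        raise UnscorablePlateError(
            f"plate {plate_id!r}: degenerate background (sd = 0)"
        )
    mean = float(survivors.mean())
    sd = float(survivors.std(ddof=1))
    outliers = set(outlier_idx)
    scored = [
        ScoredQuartet(
            quartet=q,
            corrected_value=float(values[i]),
            z=(float(values[i]) - mean) / sd,
            p=float(stats.norm.sf((values[i] - mean) / sd)),
            is_outlier=i in outliers,
        )
        for i, q in enumerate(ok)
    ]
    plate_stats = PlateStats(
        plate_id=plate_id,
        edge_effect_detected=detected,
        edge_shift=shift,
        background_mean=mean,
        background_sd=sd,
        n_outliers_removed=len(outlier_idx),
        outlier_alpha=alpha_outlier,
        edge_alpha=alpha_edge,
    )
    return plate_stats, scored
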