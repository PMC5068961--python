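"""Interaction calling across selection levels.

Each bait is screened on selective plates at several concentrations of 3AT
(a competitive inhibitor of the HIS3 reporter product), and each plate is
imaged after 7 and 10 days of growth.  A quartet significant on one plate
may be a technical artifact; demanding significance at two or more distinct
3AT levels for the same (bait, TF) pair is a semi-independent confirmation,
since the same transformant must outgrow background under progressively
stricter selection.

This module turns per-plate scored quartets into per-(bait, TF, level, day)
records, applies the consensus rule (default: p < 0.005 at >= 2 levels on
day 7), and computes threshold-sensitivity curves: the number of distinct
TFs with at least one qualifying interaction as a function of the p-value
threshold, selection level, day and required level count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .plate_io import ArrayMap, ColonyRecord, Control, PlateMeta, assemble_quartets
from .plate_stats import ScoredQuartet, UnscorablePlateError, score_plate

__all__ = [
    "InteractionRecord",
    "InteractionCall",
    "SensitivityPoint",
    "P_THRESHOLD",
    "MIN_LEVELS",
    "CALLING_DAY",
    "collect_records",
    "consensus_call",
    "sensitivity_curve",
    "score_screen",
    "records_to_frame",
]

P_THRESHOLD = 0.005
MIN_LEVELS = 2
CALLING_DAY = 7


@dataclass(frozen=True)
class InteractionRecord:
    """Significance of one (bait, TF) pair on one plate.

    ``tested=False`` marks pairs that were on an excluded plate or whose
    quartet failed QC; they are never negatives, only missing.
    """

    bait_id: str
    tf_id: str
    selection_3at_mM: int
    day: int
    z: float
    p: float
    significant: bool
    tested: bool


@dataclass(frozen=True)
class InteractionCall:
    """Consensus verdict for one (bait, TF) pair at the calling day."""

    bait_id: str
    tf_id: str
    n_levels_significant: int
    called: bool
    levels: tuple[int, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class SensitivityPoint:
    """One point of a threshold-sensitivity curve.

    ``selection_3at_mM`` is a specific level or ``None`` for the pooled
    (any-level) condition; ``n_tfs_with_hit`` counts distinct TFs with at
    least one bait called under the point's settings.
    """

    neg_log10_p: float
    selection_3at_mM: int | None
    day: int
    min_levels: int
    n_tfs_with_hit: int


def collect_records(
    scored_plates: Iterable[tuple[PlateMeta, list[ScoredQuartet]]],
    threshold: float = P_THRESHOLD,
    qc_excluded: Iterable[tuple[PlateMeta, str]] = (),
) -> list[InteractionRecord]:
    """Flatten scored plates into one record per TF quartet per plate.

    ``significant`` is strict: p < threshold.  Control occupants (empty and
    AD-only positions) never produce records.  Plates whose metadata marks
    them excluded yield ``tested=False`` records for every TF on the plate,
    as do the (plate, tf) pairs listed in ``qc_excluded``.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    records: list[InteractionRecord] = []
    for meta, scored in scored_plates:
        for sq in scored:
            if isinstance(sq.occupant, Control):
                continue
            if meta.excluded:
                records.append(
                    InteractionRecord(
                        bait_id=meta.bait_id,
                        tf_id=sq.occupant,
                        selection_3at_mM=meta.selection_3at_mM,
                        day=meta.day,
                        z=float("nan"),
                        p=float("nan"),
                        significant=False,
                        tested=False,
                    )
                )
            else:
                records.append(
                    InteractionRecord(
                        bait_id=meta.bait_id,
                        tf_id=sq.occupant,
                        selection_3at_mM=meta.selection_3at_mM,
                        day=meta.day,
                        z=sq.z,
                        p=sq.p,
                        significant=sq.p < threshold,
                        tested=True,
                    )
                )
    for meta, tf_id in qc_excluded:
        records.append(
            InteractionRecord(
                bait_id=meta.bait_id,
                tf_id=tf_id,
                selection_3at_mM=meta.selection_3at_mM,
                day=meta.day,
                z=float("nan"),
                p=float("nan"),
                significant=False,
                tested=False,
            )
        )
    return records


def consensus_call(
    records: Sequence[InteractionRecord],
    day: int = CALLING_DAY,
    min_levels: int = MIN_LEVELS,
) -> list[InteractionCall]:
    """Call (bait, TF) interactions significant at >= ``min_levels``
    distinct 3AT levels on the given day.

    Only tested records enter; a pair never tested on that day produces no
    call (missing, not negative).
    """
    days = {r.day for r in records}
    if day not in days:
        raise ValueError(f"day {day} absent from records (have {sorted(days)})")
    sig_levels: dict[tuple[str, str], set[int]] = {}
    seen: set[tuple[str, str]] = set()
    for r in records:
        if r.day != day or not r.tested:
            continue
        key = (r.bait_id, r.tf_id)
        seen.add(key)
        if r.significant:
            sig_levels.setdefault(key, set()).add(r.selection_3at_mM)
    calls = []
    for bait_id, tf_id in sorted(seen):
        levels = tuple(sorted(sig_levels.get((bait_id, tf_id), ())))
        calls.append(
            InteractionCall(
                bait_id=bait_id,
                tf_id=tf_id,
                n_levels_significant=len(levels),
                called=len(levels) >= min_levels,
                levels=levels,
            )
        )
    return calls


def sensitivity_curve(
    records: Sequence[InteractionRecord],
    p_grid: Sequence[float],
    days: Sequence[int] = (7, 10),
    min_levels_options: Sequence[int] = (1, 2, 3),
    per_level: bool = False,
) -> list[SensitivityPoint]:
    """Count TFs with >= 1 called bait over a grid of analysis settings.

    For each (threshold, day, min_levels) — and, with ``per_level=True``,
    additionally restricted to records from each single 3AT level — the
    count is of distinct TFs having at least one bait significant at
    ``min_levels`` or more 3AT levels at a p-value strictly below the
    threshold.  Pooled points carry ``selection_3at_mM=None``.
    """
    if len(p_grid) == 0:
        raise ValueError("empty p-value grid")
    tested = [r for r in records if r.tested]
    points: list[SensitivityPoint] = []
    level_conditions: list[int | None] = [None]
    if per_level:
        level_conditions += sorted({r.selection_3at_mM for r in tested})
    for day in days:
        day_recs = [r for r in tested if r.day == day]
        if not day_recs:
            continue
        for level in level_conditions:
            # Restricting to one level caps the attainable level count at 1.
            sub = day_recs if level is None else [
                r for r in day_recs if r.selection_3at_mM == level
            ]
            for thr in p_grid:
                sig: dict[tuple[str, str], set[int]] = {}
                for r in sub:
                    if r.p < thr:
                        sig.setdefault((r.bait_id, r.tf_id), set()).add(
                            r.selection_3at_mM
                        )
                for ml in min_levels_options:
                    tfs = {
                        tf for (_, tf), lv in sig.items() if len(lv) >= ml
                    }
                    points.append(
                        SensitivityPoint(
                            neg_log10_p=-math.log10(thr),
                            selection_3at_mM=level,
                            day=day,
                            min_levels=ml,
                            n_tfs_with_hit=len(tfs),
                        )
                    )
    return points


def score_screen(
    plates: Iterable[tuple[PlateMeta, list[ColonyRecord], ArrayMap]],
    threshold: float = P_THRESHOLD,
    alpha_outlier: float = 0.05,
    alpha_edge: float = 0.05,
    masks: dict[str, set[tuple[int, int]]] | None = None,
) -> list[InteractionRecord]:
    """Run the full per-plate analysis over a screen and flatten the result.

    For each plate: assemble quartets, apply quartet QC, edge-correct,
    Grubbs-screen, Z-score, then emit interaction records.  Excluded or
    unscorable plates yield ``tested=False`` records for all their TFs, as
    do individual QC-excluded TF quartets.
    """
    from .quartet_qc import qc_plate

    masks = masks or {}
    scored_plates: list[tuple[PlateMeta, list[ScoredQuartet]]] = []
    qc_excluded: list[tuple[PlateMeta, str]] = []

    def exclude_whole_plate(meta: PlateMeta, array: ArrayMap) -> None:
        scored_plates.append((replace_excluded(meta), []))
        for _, occ in array.items():
            if not isinstance(occ, Control):
                qc_excluded.append((replace_excluded(meta), occ))

    def replace_excluded(meta: PlateMeta) -> PlateMeta:
        from dataclasses import replace

        return meta if meta.excluded else replace(meta, excluded=True)

    for meta, records, array in plates:
        if meta.excluded:
            exclude_whole_plate(meta, array)
            continue
        quartets = assemble_quartets(
            records, meta, array, mask=masks.get(meta.plate_id)
        )
        values = qc_plate(quartets)
        try:
            _, scored = score_plate(
                values,
                plate_id=meta.plate_id,
                alpha_outlier=alpha_outlier,
                alpha_edge=alpha_edge,
            )
        except UnscorablePlateError:
            exclude_whole_plate(meta, array)
            continue
        scored_plates.append((meta, scored))
        for v in values:
            if not v.ok and not isinstance(v.occupant, Control):
                qc_excluded.append((meta, v.occupant))
    return collect_records(scored_plates, threshold=threshold, qc_excluded=qc_excluded)


def records_to_frame(records: Sequence[InteractionRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of interaction records."""
    return pd.DataFrame(
        {
            "bait_id": [r.bait_id for r in records],
            "tf_id": [r.tf_id for r in records],
            "selection_3at_mM": [r.selection_3at_mM for r in records],
            "day": [r.day for r in records],
            "z": [r.z for r in records],
            "p": [r.p for r in records],
            "significant": [r.significant for r in records],
            "tested": [r.tested for r in records],
        }
    )
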