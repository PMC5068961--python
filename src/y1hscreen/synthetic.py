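"""Seeded synthetic Y1H screens with known ground truth.

The generator emits Gitter-dialect plate tables with the statistical
structure the analysis pipeline assumes, so every downstream stage can be
exercised — and its error rates measured — without any external data:

* colony ln-areas are normal around a plate background mean, with a shared
  quartet-level offset (replicate spots are clones of one transformant and
  therefore correlated) plus independent per-spot noise;
* planted bait-TF interactions add a configurable ln-area boost that may
  differ per 3AT selection level, exercising the multi-level consensus rule;
* an optional additive edge effect raises (or lowers) the outermost two
  quartet rows/columns;
* artifacts are injected at configurable rates: noncircular colonies and
  missing colonies;
* negative-control array positions (untransformed cells and bare activation
  domain) receive background-only growth.

Pixel areas are ``round(exp(x))`` of the simulated ln-areas.  The same seed
always reproduces byte-identical plate tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .calling import InteractionCall
from .plate_io import (
    GRID_COLS,
    GRID_ROWS,
    QUARTET_COLS,
    QUARTET_ROWS,
    ArrayMap,
    ColonyRecord,
    Control,
    PlateMeta,
    write_gitter_table,
)

__all__ = [
    "DEFAULT_BAITS",
    "CALIBRATED_NULL_FP_RATE",
    "PlantedInteraction",
    "SimConfig",
    "GroundTruth",
    "SyntheticPlate",
    "SyntheticScreen",
    "TruthMetrics",
    "generate_screen",
    "truth_metrics",
    "write_screen",
    "read_screen",
    "small_config",
]

ARRAY_CAPACITY = QUARTET_ROWS * QUARTET_COLS  # 384 positions per source array

# Empirical per-pair false-positive rate of the full pipeline (p < 0.005,
# >= 2 of 3 levels, day 7) on null screens, fixed once by brute-force
# simulation: 100 reduced screens (small_config(n_baits=2, n_tfs=360),
# seeds 10000..10099) yielded 4 false pairs out of 72000.  The Grubbs screen
# and finite-sample background estimation make this only approximately the
# nominal multi-level binomial rate; monitoring tests compare fresh null
# screens against this value within binomial error rather than re-deriving it.
CALIBRATED_NULL_FP_RATE = 4 / 72000
NULL_CALIBRATION = {"n_screens": 100, "pairs_per_screen": 720, "seed_range": (10000, 10099)}


def _default_baits() -> dict[str, str]:
    """The 26 screened enhancer fragments: 8 melanogaster, 9 pseudoobscura
    (B8 never integrated), 9 willistoni (C8 and C11 never integrated)."""
    baits: dict[str, str] = {}
    for i in range(1, 9):
        baits[f"mel_A{i}"] = "mel"
    for i in [1, 2, 3, 4, 5, 6, 7, 9, 10]:
        baits[f"pse_B{i}"] = "pse"
    for i in [1, 2, 3, 4, 5, 6, 7, 9, 10]:
        baits[f"will_C{i}"] = "will"
    return baits


DEFAULT_BAITS = _default_baits()


@dataclass(frozen=True)
class PlantedInteraction:
    """A true bait-TF interaction with its ln-area boost per 3AT level.

    Levels absent from ``delta_per_level`` confer no boost, so an
    interaction can be real at 10 and 20 mM yet invisible at 40 mM.
    """

    bait_id: str
    tf_id: str
    delta_per_level: dict[int, float]


@dataclass
class SimConfig:
    """Study conditions for a synthetic screen.

    Defaults mirror the screened study: 670 TFs split over two 384-position
    source arrays, 26 baits across three species, three 3AT levels per bait,
    imaging after 7 and 10 days.  ``mu0``/``sigma0`` set the background
    ln-area distribution (exp(5.5) is roughly a 245-pixel colony);
    ``quartet_sd_frac`` is the fraction of sigma0 carried by the shared
    quartet-level offset.
    """

    n_tfs: int = 670
    baits: dict[str, str] = field(default_factory=_default_baits)
    levels_per_bait: dict[str, tuple[int, ...]] | None = None
    default_levels: tuple[int, ...] = (10, 20, 40)
    days: tuple[int, ...] = (7, 10)
    mu0: float = 5.5
    sigma0: float = 0.3
    day10_shift: float = 0.4
    quartet_sd_frac: float = 0.5
    edge_effect_delta: float = 0.0
    interactions: list[PlantedInteraction] = field(default_factory=list)
    noncircular_rate: float = 0.01
    missing_rate: float = 0.01
    n_ad_only_per_array: int = 8
    excluded_plates: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        for rate in (self.noncircular_rate, self.missing_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("artifact rates must lie in [0, 1]")
        if not (0.0 <= self.quartet_sd_frac <= 1.0):
            raise ValueError("quartet_sd_frac must lie in [0, 1]")
        for it in self.interactions:
            if any(d < 0 for d in it.delta_per_level.values()):
                raise ValueError("planted shifts must be non-negative")

    def levels_for(self, bait_id: str) -> tuple[int, ...]:
        if self.levels_per_bait and bait_id in self.levels_per_bait:
            return self.levels_per_bait[bait_id]
        return self.default_levels

    def tf_ids(self) -> list[str]:
        return [f"TF{i:04d}" for i in range(1, self.n_tfs + 1)]

    def build_arrays(self) -> dict[str, ArrayMap]:
        capacity = ARRAY_CAPACITY - self.n_ad_only_per_array
        tfs = self.tf_ids()
        n_arrays = max(1, math.ceil(len(tfs) / capacity))
        arrays = {}
        for k in range(n_arrays):
            aid = f"p{k + 1}"
            arrays[aid] = ArrayMap.from_tf_list(
                aid,
                tfs[k * capacity : (k + 1) * capacity],
                n_ad_only=self.n_ad_only_per_array,
            )
        return arrays


@dataclass
class GroundTruth:
    """What the generator planted: interactions, injected artifacts, and the
    plates carrying an edge effect."""

    interactions: list[PlantedInteraction]
    artifact_wells: list[tuple[str, int, int, str]]  # plate_id, row, col, kind
    edge_affected_plates: list[str]

    @property
    def planted_pairs(self) -> set[tuple[str, str]]:
        return {(it.bait_id, it.tf_id) for it in self.interactions}


@dataclass
class SyntheticPlate:
    meta: PlateMeta
    records: list[ColonyRecord]
    array: ArrayMap


@dataclass
class SyntheticScreen:
    plates: list[SyntheticPlate]
    arrays: dict[str, ArrayMap]
    truth: GroundTruth
    config: SimConfig


def generate_screen(config: SimConfig, seed: int) -> SyntheticScreen:
    """Generate one full synthetic screen.

    One plate is produced per (bait, 3AT level, day, source array).  The
    quartet-level offset of a plate is shared between its day-7 and day-10
    images (the same physical plate is imaged twice); per-spot noise is
    drawn independently per day.
    """
    arrays = config.build_arrays()
    tf_positions: dict[str, dict[str, tuple[int, int]]] = {}
    for aid, arr in arrays.items():
        tf_positions[aid] = {
            occ: pos for pos, occ in arr.items() if not isinstance(occ, Control)
        }
    all_tfs = {tf for pos in tf_positions.values() for tf in pos}
    for it in config.interactions:
        if it.tf_id not in all_tfs:
            raise ValueError(f"planted TF {it.tf_id!r} not on any source array")
        if it.bait_id not in config.baits:
            raise ValueError(f"planted bait {it.bait_id!r} not in the bait set")

    plants: dict[tuple[str, str], dict[int, float]] = {
        (it.bait_id, it.tf_id): it.delta_per_level for it in config.interactions
    }
    sigma_q = config.quartet_sd_frac * config.sigma0
    sigma_w = math.sqrt(max(config.sigma0**2 - sigma_q**2, 0.0))

    rng = np.random.default_rng(seed)
    plates: list[SyntheticPlate] = []
    artifacts: list[tuple[str, int, int, str]] = []
    edge_plates: list[str] = []

    qrows = np.arange(1, QUARTET_ROWS + 1)
    qcols = np.arange(1, QUARTET_COLS + 1)
    edge_mask_q = (
        np.isin(qrows, (1, 2, 15, 16))[:, None]
        | np.isin(qcols, (1, 2, 23, 24))[None, :]
    )

    for bait_id in sorted(config.baits):
        species = config.baits[bait_id]
        for level in config.levels_for(bait_id):
            for aid in sorted(arrays):
                # shared across the two imaging days of this physical plate
                q_offset = rng.normal(0.0, sigma_q, (QUARTET_ROWS, QUARTET_COLS))
                delta_grid = np.zeros((QUARTET_ROWS, QUARTET_COLS))
                for tf, pos in tf_positions[aid].items():
                    d = plants.get((bait_id, tf))
                    if d:
                        delta_grid[pos[0] - 1, pos[1] - 1] = d.get(level, 0.0)
                base_q = (
                    config.mu0
                    + q_offset
                    + delta_grid
                    + config.edge_effect_delta * edge_mask_q
                )
                for day in sorted(config.days):
                    plate_id = f"{bait_id}_{level}mM_d{day}_{aid}"
                    excluded = (bait_id, aid) in config.excluded_plates
                    meta = PlateMeta(
                        plate_id=plate_id,
                        bait_id=bait_id,
                        species=species,
                        selection_3at_mM=level,
                        day=day,
                        tf_array_id=aid,
                        excluded=excluded,
                    )
                    mu_wells = np.repeat(
                        np.repeat(base_q, 2, axis=0), 2, axis=1
                    ) + (config.day10_shift if day == 10 else 0.0)
                    x = mu_wells + rng.normal(0.0, sigma_w, (GRID_ROWS, GRID_COLS))
                    areas = np.maximum(np.rint(np.exp(x)).astype(int), 1)
                    missing = rng.random((GRID_ROWS, GRID_COLS)) < config.missing_rate
                    noncirc = rng.random((GRID_ROWS, GRID_COLS)) < config.noncircular_rate
                    records = []
                    for r in range(GRID_ROWS):
                        for c in range(GRID_COLS):
                            if missing[r, c]:
                                records.append(
                                    ColonyRecord(r + 1, c + 1, 0, True, False)
                                )
                                artifacts.append((plate_id, r + 1, c + 1, "missing"))
                            else:
                                circ = not noncirc[r, c]
                                if not circ:
                                    artifacts.append(
                                        (plate_id, r + 1, c + 1, "noncircular")
                                    )
                                records.append(
                                    ColonyRecord(
                                        r + 1, c + 1, int(areas[r, c]), circ, True
                                    )
                                )
                    if config.edge_effect_delta != 0.0:
                        edge_plates.append(plate_id)
                    plates.append(SyntheticPlate(meta=meta, records=records, array=arrays[aid]))

    truth = GroundTruth(
        interactions=list(config.interactions),
        artifact_wells=artifacts,
        edge_affected_plates=edge_plates,
    )
    return SyntheticScreen(plates=plates, arrays=arrays, truth=truth, config=config)


@dataclass(frozen=True)
class TruthMetrics:
    """How the pipeline's calls compare with what was planted."""

    recall: float
    n_planted: int
    n_recovered: int
    false_positives: tuple[tuple[str, str], ...]

    @property
    def n_false_positives(self) -> int:
        return len(self.false_positives)


def truth_metrics(
    calls: Sequence[InteractionCall], truth: GroundTruth
) -> TruthMetrics:
    """Recall and false positives of a call set against the planted truth.

    Recall is over all planted pairs; a plant whose boost was confined to a
    single 3AT level is not expected to survive the consensus rule and will
    depress recall by construction.
    """
    called = {(c.bait_id, c.tf_id) for c in calls if c.called}
    planted = truth.planted_pairs
    recovered = called & planted
    fp = tuple(sorted(called - planted))
    recall = len(recovered) / len(planted) if planted else float("nan")
    return TruthMetrics(
        recall=recall,
        n_planted=len(planted),
        n_recovered=len(recovered),
        false_positives=fp,
    )


def per_delta_detection(
    calls: Sequence[InteractionCall], truth: GroundTruth
) -> dict[float, tuple[int, int]]:
    """Detection table keyed by a plant's maximum per-level boost:
    delta -> (n recovered, n planted)."""
    called = {(c.bait_id, c.tf_id) for c in calls if c.called}
    table: dict[float, list[int]] = {}
    for it in truth.interactions:
        d = max(it.delta_per_level.values(), default=0.0)
        hit = (it.bait_id, it.tf_id) in called
        entry = table.setdefault(d, [0, 0])
        entry[0] += int(hit)
        entry[1] += 1
    return {d: (v[0], v[1]) for d, v in sorted(table.items())}


# ---------------------------------------------------------------------------
# On-disk screen layout: plate TSVs + manifest YAML + truth table

def write_screen(screen: SyntheticScreen, outdir) -> Path:
    """Write a screen as plate TSVs, array-map TSVs, a YAML manifest and a
    ground-truth table; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"plates": [], "arrays": {}, "baits": dict(screen.config.baits)}
    for aid, arr in screen.arrays.items():
        fname = f"array_{aid}.tsv"
        with open(outdir / fname, "w", encoding="utf-8") as fh:
            fh.write("qrow\tqcol\toccupant\n")
            for (r, c), occ in sorted(arr.items()):
                name = occ.value if isinstance(occ, Control) else occ
                fh.write(f"{r}\t{c}\t{name}\n")
        manifest["arrays"][aid] = fname
    for plate in screen.plates:
        fname = f"{plate.meta.plate_id}.tsv"
        with open(outdir / fname, "w", encoding="utf-8") as fh:
            write_gitter_table(plate.records, fh)
        manifest["plates"].append(
            {
                "plate_id": plate.meta.plate_id,
                "file": fname,
                "bait_id": plate.meta.bait_id,
                "species": plate.meta.species,
                "selection_3at_mM": int(plate.meta.selection_3at_mM),
                "day": int(plate.meta.day),
                "tf_array_id": plate.meta.tf_array_id,
                "excluded": bool(plate.meta.excluded),
            }
        )
    with open(outdir / "truth.tsv", "w", encoding="utf-8") as fh:
        fh.write("bait_id\ttf_id\tlevel\tdelta\n")
        for it in screen.truth.interactions:
            for level, delta in sorted(it.delta_per_level.items()):
                fh.write(f"{it.bait_id}\t{it.tf_id}\t{level}\t{delta}\n")
    manifest_path = outdir / "manifest.yaml"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path


def read_screen(manifest_path) -> list[tuple[PlateMeta, list[ColonyRecord], ArrayMap]]:
    """Load plates written by :func:`write_screen` (or hand-built to the same
    manifest layout) for analysis."""
    from .plate_io import read_gitter_table

    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    with open(manifest_path, "r", encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    arrays: dict[str, ArrayMap] = {}
    control_names = {c.value for c in Control}
    for aid, fname in manifest["arrays"].items():
        assignments: dict[tuple[int, int], object] = {}
        with open(root / fname, "r", encoding="utf-8") as fh:
            next(fh)  # header
            for line in fh:
                r, c, occ = line.rstrip("\n").split("\t")
                assignments[(int(r), int(c))] = (
                    Control(occ) if occ in control_names else occ
                )
        arrays[aid] = ArrayMap(aid, assignments)
    plates = []
    for entry in manifest["plates"]:
        meta = PlateMeta(
            plate_id=entry["plate_id"],
            bait_id=entry["bait_id"],
            species=entry["species"],
            selection_3at_mM=entry["selection_3at_mM"],
            day=entry["day"],
            tf_array_id=entry["tf_array_id"],
            excluded=entry["excluded"],
        )
        records = read_gitter_table(root / entry["file"])
        plates.append((meta, records, arrays[entry["tf_array_id"]]))
    return plates


def small_config(
    n_baits: int = 2,
    n_tfs: int = 360,
    days: tuple[int, ...] = (7,),
    **overrides,
) -> SimConfig:
    """A reduced screen (single source array, few baits) for simulation
    studies where the full 312-plate screen would be wasteful."""
    baits = dict(list(_default_baits().items())[:n_baits])
    return SimConfig(n_tfs=n_tfs, baits=baits, days=days, **overrides)
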