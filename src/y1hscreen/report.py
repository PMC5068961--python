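"""Screen-level summaries and integration with RNAi phenotype data.

Turns per-(bait, TF) interaction calls into per-TF hit profiles (how many
enhancer fragments from each species a TF bound), headline counts for the
whole screen, and the overlap between biochemical (Y1H) hits and TFs whose
RNAi knockdown altered adult abdominal pigmentation.  RNAi phenotype
classification is wet-lab input and enters only as a pre-coded table.

Shipped under ``y1hscreen/data`` are the published hit matrix, RNAi
phenotype table and nuclear-receptor annotation, so the headline screen
counts are reproducible offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .calling import InteractionCall

__all__ = [
    "SPECIES",
    "TfHitProfile",
    "ScreenSummary",
    "count_tests",
    "summarize_hits",
    "summarize_profiles",
    "profiles_from_calls",
    "integrate_rnai",
    "load_hit_matrix",
    "write_hit_matrix",
    "load_rnai_table",
    "load_nuclear_receptors",
    "bundled_data_path",
]

SPECIES = ("mel", "pse", "will")

RNAI_CATEGORIES = frozenset(
    {"A6_female_only", "A5_A6_reduced", "multi_segment_reduced", "increased"}
)


@dataclass(frozen=True)
class TfHitProfile:
    """Per-TF hit profile across bait species.

    ``rnai_phenotype`` is True/False for TFs present in the RNAi table and
    None for TFs never tested by RNAi; ``rnai_category`` holds phenotype
    category codes for affected TFs.
    """

    tf_id: str
    hits_per_species: dict[str, int]
    is_nuclear_receptor: bool = False
    rnai_phenotype: bool | None = None
    rnai_category: frozenset[str] = field(default_factory=frozenset)

    @property
    def total_fragments_hit(self) -> int:
        return sum(self.hits_per_species.values())


@dataclass(frozen=True)
class ScreenSummary:
    """Headline counts for one screen."""

    n_tests: int
    n_tfs_hit: int
    n_tfs_multi_fragment: int
    per_species_tf_counts: dict[str, int]
    max_fragment_tfs: tuple[str, ...]
    max_fragment_count: int
    n_overlap_rnai: int | None = None
    n_nuclear_receptors_hit: int | None = None


def count_tests(n_tfs: int, n_baits: int, exclusions: Iterable[int] = ()) -> int:
    """Number of unique bait-prey tests: n_tfs x n_baits, minus any
    excluded pair counts (e.g. a half-array lost to contamination)."""
    if n_tfs < 0 or n_baits < 0:
        raise ValueError("counts must be non-negative")
    return n_tfs * n_baits - sum(exclusions)


def profiles_from_calls(
    calls: Sequence[InteractionCall],
    bait_species: Mapping[str, str],
) -> list[TfHitProfile]:
    """Aggregate positive interaction calls into per-TF species profiles."""
    per_tf: dict[str, dict[str, int]] = {}
    for call in calls:
        if not call.called:
            continue
        if call.bait_id not in bait_species:
            raise KeyError(f"bait {call.bait_id!r} has no species mapping")
        sp = bait_species[call.bait_id]
        if sp not in SPECIES:
            raise ValueError(f"unknown species {sp!r} for bait {call.bait_id!r}")
        counts = per_tf.setdefault(call.tf_id, {s: 0 for s in SPECIES})
        counts[sp] += 1
    return [
        TfHitProfile(tf_id=tf, hits_per_species=counts)
        for tf, counts in sorted(per_tf.items())
    ]


def summarize_profiles(
    profiles: Sequence[TfHitProfile],
    n_tfs: int = 670,
    n_baits: int = 26,
) -> ScreenSummary:
    """Headline counts from per-TF profiles.

    Distinct-TF species counts tally a TF once per species it hits; the
    maximum-fragment TF is reported with ties broken by listing all,
    sorted by identifier.
    """
    hit = [p for p in profiles if p.total_fragments_hit > 0]
    species_counts = {
        sp: sum(1 for p in hit if p.hits_per_species.get(sp, 0) > 0)
        for sp in SPECIES
    }
    multi = [p for p in hit if p.total_fragments_hit > 1]
    if hit:
        max_count = max(p.total_fragments_hit for p in hit)
        max_tfs = tuple(
            sorted(p.tf_id for p in hit if p.total_fragments_hit == max_count)
        )
    else:
        max_count = 0
        max_tfs = ()
    overlap = None
    if any(p.rnai_phenotype is not None for p in profiles):
        overlap = sum(1 for p in hit if p.rnai_phenotype)
    nr = None
    if any(p.is_nuclear_receptor for p in profiles):
        nr = sum(1 for p in hit if p.is_nuclear_receptor)
    return ScreenSummary(
        n_tests=count_tests(n_tfs, n_baits),
        n_tfs_hit=len(hit),
        n_tfs_multi_fragment=len(multi),
        per_species_tf_counts=species_counts,
        max_fragment_tfs=max_tfs,
        max_fragment_count=max_count,
        n_overlap_rnai=overlap,
        n_nuclear_receptors_hit=nr,
    )


def summarize_hits(
    calls: Sequence[InteractionCall],
    bait_species: Mapping[str, str],
    n_tfs: int = 670,
    n_baits: int = 26,
) -> tuple[list[TfHitProfile], ScreenSummary]:
    """Build per-TF profiles from interaction calls and summarise them."""
    profiles = profiles_from_calls(calls, bait_species)
    return profiles, summarize_profiles(profiles, n_tfs=n_tfs, n_baits=n_baits)


def integrate_rnai(
    profiles: Sequence[TfHitProfile],
    rnai_table: Mapping[str, tuple[bool, frozenset[str]]],
    nuclear_receptors: Iterable[str] = (),
) -> tuple[set[str], list[TfHitProfile]]:
    """Annotate profiles with RNAi outcomes and compute the dual-evidence set.

    The overlap is the set of TFs with at least one positive Y1H call whose
    knockdown affected pigmentation.  TFs absent from ``rnai_table`` keep
    ``rnai_phenotype=None`` ("not tested by RNAi").
    """
    nr = set(nuclear_receptors)
    annotated = []
    overlap: set[str] = set()
    for p in profiles:
        entry = rnai_table.get(p.tf_id)
        if entry is None:
            q = replace(p, is_nuclear_receptor=p.tf_id in nr)
        else:
            affected, cats = entry
            q = replace(
                p,
                is_nuclear_receptor=p.tf_id in nr,
                rnai_phenotype=affected,
                rnai_category=frozenset(cats),
            )
            if affected and p.total_fragments_hit > 0:
                overlap.add(p.tf_id)
        annotated.append(q)
    return overlap, annotated


# ---------------------------------------------------------------------------
# Table I/O

def load_hit_matrix(source) -> list[TfHitProfile]:
    """Read a TF x species fragment-count matrix TSV into profiles."""
    lines = _read_lines(source)
    header = lines[0].split("\t")
    if header[0] != "tf_id" or set(header[1:]) != set(SPECIES):
        raise ValueError(f"unexpected hit-matrix header {header}")
    order = header[1:]
    profiles = []
    seen = set()
    for line in lines[1:]:
        parts = line.split("\t")
        tf = parts[0]
        if tf in seen:
            raise ValueError(f"duplicate TF row {tf!r}")
        seen.add(tf)
        counts = {sp: int(v) for sp, v in zip(order, parts[1:])}
        profiles.append(TfHitProfile(tf_id=tf, hits_per_species=counts))
    return profiles


def write_hit_matrix(profiles: Sequence[TfHitProfile], sink) -> None:
    """Emit profiles as a TF x species matrix re-readable by
    :func:`load_hit_matrix`."""
    fh = sink if hasattr(sink, "write") else open(sink, "w", encoding="utf-8")
    close = not hasattr(sink, "write")
    try:
        fh.write("tf_id\t" + "\t".join(SPECIES) + "\n")
        for p in profiles:
            counts = "\t".join(str(p.hits_per_species.get(sp, 0)) for sp in SPECIES)
            fh.write(f"{p.tf_id}\t{counts}\n")
    finally:
        if close:
            fh.close()


def load_rnai_table(source) -> dict[str, tuple[bool, frozenset[str]]]:
    """Read the RNAi phenotype TSV (tf_id, affected, categories)."""
    lines = _read_lines(source)
    header = lines[0].split("\t")
    if header[:2] != ["tf_id", "affected"]:
        raise ValueError(f"unexpected RNAi-table header {header}")
    table: dict[str, tuple[bool, frozenset[str]]] = {}
    for line in lines[1:]:
        parts = line.split("\t")
        tf = parts[0]
        if tf in table:
            raise ValueError(f"duplicate RNAi row for {tf!r}")
        affected = parts[1].strip() in ("1", "true", "True", "yes")
        cats: frozenset[str] = frozenset()
        if len(parts) > 2 and parts[2].strip():
            cats = frozenset(parts[2].strip().split(";"))
            unknown = cats - RNAI_CATEGORIES
            if unknown:
                raise ValueError(f"unknown RNAi categories {sorted(unknown)}")
        table[tf] = (affected, cats)
    return table


def load_nuclear_receptors(source) -> set[str]:
    """Read the nuclear-receptor annotation TSV into a set of TF ids."""
    lines = _read_lines(source)
    out = set()
    for line in lines[1:]:
        parts = line.split("\t")
        if len(parts) > 1 and parts[1].strip() in ("1", "true", "True", "yes"):
            out.add(parts[0])
    return out


def bundled_data_path(name: str) -> Path:
    """Path to a data table shipped with the package."""
    return Path(str(resources.files("y1hscreen").joinpath("data", name)))


def _read_lines(source) -> list[str]:
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    return [
        ln
        for ln in (raw.strip("\r") for raw in text.split("\n"))
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
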