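"""Cross-cohort miRNA fold-change integration.

Tumour-versus-normal microarray cohorts report linear fold changes per
miRNA. This module harmonizes miRNA names through a static alias table,
applies a minimum fold-change rule (default 1.5x in either direction),
consolidates the per-cohort calls into a unified direction list, and
computes exact Venn-region memberships for set comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

__all__ = [
    "FoldChangeTable",
    "AliasTable",
    "DirectionCall",
    "VennResult",
    "harmonize_names",
    "fold_change_filter",
    "consolidate_cohorts",
    "set_overlap",
    "direction_consistency",
]


@dataclass
class FoldChangeTable:
    """Per-cohort linear fold changes (tumour over normal) keyed by miRNA id."""

    cohort_id: str
    entries: dict[str, float]

    def __post_init__(self) -> None:
        bad = [m for m, fc in self.entries.items() if not fc > 0]
        if bad:
            raise ValueError(
                f"{self.cohort_id}: non-positive fold change for {bad[:5]}"
            )


@dataclass
class AliasTable:
    """Functional raw-name -> canonical-id mapping (one target per raw name)."""

    mapping: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AliasTable":
        mapping: dict[str, str] = {}
        for raw, canon in pairs:
            if raw in mapping and mapping[raw] != canon:
                raise ValueError(
                    f"conflicting aliases for {raw!r}: {mapping[raw]!r} vs {canon!r}"
                )
            mapping[raw] = canon
        return cls(mapping)

    def resolve(self, name: str) -> str:
        return self.mapping.get(name, name)


def default_alias_table() -> AliasTable:
    """The small alias table shipped with the package (miRBase-v20 style).

    Real miRBase synchronization is out of scope; this covers the common
    precursor/mature spellings seen in legacy microarray cohorts.
    """
    import csv
    from importlib.resources import files

    text = files("mirreg.data").joinpath("aliases.tsv").read_text().splitlines()
    reader = csv.DictReader(text, delimiter="\t")
    return AliasTable.from_pairs(
        (row["raw_name"], row["canonical_id"]) for row in reader
    )


def harmonize_names(
    names: Sequence[str], aliases: AliasTable
) -> tuple[list[str], list[str]]:
    """Map raw names to canonical ids; unmapped names pass through unchanged.

    Returns (canonical names, unmapped report). The mapping is idempotent:
    canonical ids resolve to themselves. Output length equals input length —
    unknown names are reported, never dropped.
    """
    canonical: list[str] = []
    unmapped: list[str] = []
    known_targets = set(aliases.mapping.values())
    for name in names:
        resolved = aliases.resolve(name)
        canonical.append(resolved)
        if name not in aliases.mapping and name not in known_targets:
            unmapped.append(name)
    return canonical, unmapped


@dataclass(frozen=True)
class DirectionCall:
    """A miRNA's expression direction with its supporting cohorts."""

    mirna_id: str
    direction: str  # "up" | "down"
    cohorts_supporting: tuple[str, ...] = ()
    discordant: bool = False


def fold_change_filter(
    table: FoldChangeTable, threshold: float = 1.5
) -> list[DirectionCall]:
    """Keep miRNAs changed at least ``threshold``-fold in either direction.

    fc >= threshold is called up; fc <= 1/threshold is called down; the band
    in between is excluded. Applied on the linear ratio scale.
    """
    if not threshold > 1:
        raise ValueError("threshold must exceed 1")
    calls: list[DirectionCall] = []
    for mirna, fc in table.entries.items():
        if fc >= threshold:
            calls.append(DirectionCall(mirna, "up", (table.cohort_id,)))
        elif fc <= 1.0 / threshold:
            calls.append(DirectionCall(mirna, "down", (table.cohort_id,)))
    return calls


def consolidate_cohorts(
    calls: Sequence[Sequence[DirectionCall]],
) -> list[DirectionCall]:
    """Union per-cohort direction calls into one list, flagging conflicts.

    A miRNA called in both directions across cohorts is kept with
    ``discordant=True`` (and excluded from downstream consistency checks);
    concordant calls accumulate their supporting cohorts.
    """
    by_mirna: dict[str, list[DirectionCall]] = {}
    for cohort_calls in calls:
        for call in cohort_calls:
            by_mirna.setdefault(call.mirna_id, []).append(call)
    unified: list[DirectionCall] = []
    for mirna in sorted(by_mirna):
        group = by_mirna[mirna]
        directions = {c.direction for c in group}
        supporters = tuple(
            sorted({cid for c in group for cid in c.cohorts_supporting})
        )
        if len(directions) > 1:
            unified.append(DirectionCall(mirna, "discordant", supporters, True))
        else:
            unified.append(DirectionCall(mirna, group[0].direction, supporters))
    return unified


@dataclass
class VennResult:
    """Exact Venn-region memberships for 2-4 named sets."""

    set_names: tuple[str, ...]
    regions: dict[frozenset, set]  # region key = names containing the elements

    def size(self, *names: str) -> int:
        """Size of the exclusive region belonging to exactly these sets."""
        return len(self.regions.get(frozenset(names), set()))

    def intersection(self, *names: str) -> set:
        """Full (non-exclusive) intersection of the named sets."""
        members: set = set()
        target = frozenset(names)
        for key, elems in self.regions.items():
            if target <= key:
                members |= elems
        return members

    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())


def set_overlap(sets: Mapping[str, Iterable]) -> VennResult:
    """Compute exact Venn-region memberships for 2 to 4 named sets."""
    named = {name: set(values) for name, values in sets.items()}
    if not 2 <= len(named) <= 4:
        raise ValueError("set_overlap handles 2 to 4 sets")
    names = tuple(named)
    regions: dict[frozenset, set] = {}
    universe = set().union(*named.values())
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions[frozenset(combo)] = set()
    for elem in universe:
        membership = frozenset(n for n in names if elem in named[n])
        regions[membership].add(elem)
    return VennResult(set_names=names, regions=regions)


def direction_consistency(
    tumour_call: DirectionCall, cohort_calls: Sequence[DirectionCall]
) -> bool:
    """True iff the tumour direction is confirmed by the unified cohort list.

    Requires presence in the unified list, a non-discordant cohort call, and
    matching direction (e.g. repressed in driver-high tumours AND low versus
    normal testis).
    """
    for call in cohort_calls:
        if call.mirna_id == tumour_call.mirna_id:
            return (not call.discordant) and call.direction == tumour_call.direction
    return False
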