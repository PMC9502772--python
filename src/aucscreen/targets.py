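"""Aggregate hit compounds by annotated target.

Multi-target compounds are counted once per annotated target. Groups are
keyed by (target, direction) and sorted by descending hit count then
target name, so targets with overlapping hits surface first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import GroupingError
from .hits import Direction, HitCall
from .model import CompoundRecord, Role

__all__ = ["TargetGroup", "group_hits", "completeness_flag"]

#: Groups with fewer hits than this are retained but flagged as singletons.
MIN_REPORTED_GROUP_SIZE = 2


@dataclass(frozen=True)
class TargetGroup:
    target: str
    direction: Direction
    compound_ids: tuple[str, ...]
    n_in_library: int

    @property
    def n_hits(self) -> int:
        return len(self.compound_ids)

    @property
    def singleton(self) -> bool:
        return self.n_hits < MIN_REPORTED_GROUP_SIZE


def group_hits(
    hits: Iterable[HitCall], annotations: Iterable[CompoundRecord]
) -> list[TargetGroup]:
    """One group per (target, direction) over the DECREASE/INCREASE hits.

    Raises :class:`GroupingError` for any hit compound without an
    annotation record.
    """
    by_id = {a.compound_id: a for a in annotations}
    library_counts: dict[str, int] = {}
    for a in by_id.values():
        if a.role is Role.LIBRARY:
            for t in a.targets:
                library_counts[t] = library_counts.get(t, 0) + 1

    members: dict[tuple[str, Direction], list[str]] = {}
    for hit in hits:
        if hit.direction is Direction.NONE:
            continue
        ann = by_id.get(hit.compound_id)
        if ann is None:
            raise GroupingError(
                f"hit compound {hit.compound_id!r} has no annotation record"
            )
        for target in ann.targets:
            members.setdefault((target, hit.direction), []).append(
                hit.compound_id
            )

    groups = [
        TargetGroup(
            target=target,
            direction=direction,
            compound_ids=tuple(sorted(ids)),
            n_in_library=library_counts.get(target, 0),
        )
        for (target, direction), ids in members.items()
    ]
    groups.sort(key=lambda g: (g.direction.value, -g.n_hits, g.target))
    return groups


def completeness_flag(group: TargetGroup) -> bool:
    """True iff every library compound annotated to this target is a hit."""
    return group.n_hits == group.n_in_library
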