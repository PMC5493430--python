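"""Pathway integration: collapse redundant pathways into delegate-led groups.

Many significant pathways can owe their significance to one shared set of
expressed proteins.  The integration loop repeatedly picks the remaining
pathway with the largest mapped-protein set as a *delegate*, absorbs every
remaining pathway whose mapped set it contains, and finally keeps only the
groups whose delegate is itself significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .statistic import PathwayTestResult

__all__ = ["PathwayGroup", "subset_relation", "integrate_pathways"]


@dataclass(frozen=True)
class PathwayGroup:
    """A delegate pathway plus the pathways it absorbs (delegate first)."""

    delegate_id: str
    member_ids: tuple[str, ...]
    delegate_p: float
    retained: bool


def subset_relation(a: Iterable[str], b: Iterable[str]) -> bool:
    """True iff a ⊆ b (equality counts)."""
    return set(a) <= set(b)


def integrate_pathways(
    results: Sequence[PathwayTestResult],
    alpha: float = 0.05,
    use_qualified: bool = False,
) -> list[PathwayGroup]:
    """Partition tested pathways into delegate-led groups.

    The subset relation is evaluated on mapped-protein sets (pathway ∩
    data), or on the qualified (non-zero) subsets when ``use_qualified``.
    Ties on the maximal mapped-set size break lexicographically by pathway
    id.  Every group is returned; ``retained`` marks those whose delegate
    has p ≤ alpha.  Groups are ordered by size descending, then delegate id.
    """
    ids = [r.pathway_id for r in results]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate pathway ids in results")
    protein_sets = {
        r.pathway_id: (r.qualified_mapped() if use_qualified else r.mapped)
        for r in results
    }
    p_of = {r.pathway_id: r.p_value for r in results}
    remaining = set(ids)
    groups: list[PathwayGroup] = []
    while remaining:
        delegate = min(remaining, key=lambda pid: (-len(protein_sets[pid]), pid))
        absorbed = sorted(
            pid
            for pid in remaining
            if pid != delegate
            and subset_relation(protein_sets[pid], protein_sets[delegate])
        )
        remaining.discard(delegate)
        remaining.difference_update(absorbed)
        groups.append(
            PathwayGroup(
                delegate_id=delegate,
                member_ids=(delegate, *absorbed),
                delegate_p=p_of[delegate],
                retained=p_of[delegate] <= alpha,
            )
        )
    groups.sort(key=lambda g: (-len(g.member_ids), g.delegate_id))
    return groups
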