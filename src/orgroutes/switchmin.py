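"""Organism-switch detection and minimization along a reaction sequence.

A route may need more than one organism: when no single selected organism
possesses all reactions seen since the last hand-off, the route *switches*
organisms.  The detector maintains a running organism set S: it starts as the
selected organisms containing the first reaction and is intersected with each
subsequent reaction's organism set.  When S would become empty, one switch is
counted, the finished segment is emitted with its final (maximal) organism
set, and S restarts from the selected organisms containing the new reaction.

This greedy fold yields the minimum possible number of switches for the
sequence (the classic interval-partition greedy argument), and each emitted
segment set is maximal: no further organism within the selection contains
every reaction of that segment.  :func:`min_segments_oracle` checks the
minimality claim exhaustively on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import EmptySelectionError, OracleBoundError
from .orgsets import OrgBitset, OrganismMatrix, orgs_for_reaction

__all__ = [
    "Segment",
    "SwitchState",
    "init_switch_state",
    "extend_switch_state",
    "segment_route",
    "min_segments_oracle",
]


@dataclass(frozen=True)
class Segment:
    """A maximal run of consecutive reactions sharing at least one organism,
    together with the maximal organism set that contains all of them."""

    organisms: OrgBitset
    reactions: tuple[str, ...]


@dataclass(frozen=True)
class SwitchState:
    """Running state of the switch detector.

    ``S`` is the current running intersection (never empty between
    operations); ``closed`` holds finished segments; ``current_reactions``
    the open segment's reactions.
    """

    user_set: OrgBitset
    S: OrgBitset
    switches: int
    closed: tuple[Segment, ...]
    current_reactions: tuple[str, ...]

    def segments(self) -> tuple[Segment, ...]:
        """All segments, closing the currently open one."""
        if not self.current_reactions:
            return self.closed
        return self.closed + (Segment(self.S, self.current_reactions),)


def _community_row(
    matrix: OrganismMatrix, user_set: OrgBitset, reaction_id: str
) -> OrgBitset:
    row = orgs_for_reaction(matrix, reaction_id, user_set)
    if row.is_empty():
        raise EmptySelectionError(
            f"reaction {reaction_id!r} occurs in no selected organism"
        )
    return row


def init_switch_state(
    matrix: OrganismMatrix, user_set: OrgBitset, first_reaction_id: str
) -> SwitchState:
    """Start the detector: S is the selected organisms containing the first
    reaction; zero switches; one open segment."""
    row = _community_row(matrix, user_set, first_reaction_id)
    return SwitchState(
        user_set=user_set,
        S=row,
        switches=0,
        closed=(),
        current_reactions=(first_reaction_id,),
    )


def extend_switch_state(
    state: SwitchState, matrix: OrganismMatrix, reaction_id: str
) -> SwitchState:
    """Extend the route by one reaction, updating S and the switch count."""
    row = _community_row(matrix, state.user_set, reaction_id)
    inter = state.S & row
    if not inter.is_empty():
        return SwitchState(
            user_set=state.user_set,
            S=inter,
            switches=state.switches,
            closed=state.closed,
            current_reactions=state.current_reactions + (reaction_id,),
        )
    return SwitchState(
        user_set=state.user_set,
        S=row,
        switches=state.switches + 1,
        closed=state.closed + (Segment(state.S, state.current_reactions),),
        current_reactions=(reaction_id,),
    )


def segment_route(
    matrix: OrganismMatrix, user_set: OrgBitset, reaction_ids: Sequence[str]
) -> tuple[int, tuple[Segment, ...]]:
    """Greedy segmentation of a whole reaction sequence.

    Returns ``(switch_count, segments)``; the switch count is minimal and
    each segment's organism set is maximal.  An empty sequence yields zero
    switches and no segments.
    """
    if not reaction_ids:
        return 0, ()
    state = init_switch_state(matrix, user_set, reaction_ids[0])
    for rid in reaction_ids[1:]:
        state = extend_switch_state(state, matrix, rid)
    return state.switches, state.segments()


def min_segments_oracle(
    matrix: OrganismMatrix, user_set: OrgBitset, reaction_ids: Sequence[str]
) -> int:
    """Exhaustive minimum number of contiguous segments such that each
    segment's reactions share at least one selected organism.

    Enumerates all 2^(n-1) contiguous partitions; intended as an independent
    check of the greedy detector on short routes (n <= 16).
    """
    n = len(reaction_ids)
    if n == 0:
        return 0
    if n > 16:
        raise OracleBoundError(f"route of length {n} exceeds exhaustive bound 16")
    rows = [_community_row(matrix, user_set, rid) for rid in reaction_ids]
    best = n
    for cuts in range(1 << (n - 1)):
        segments = 1 + cuts.bit_count()
        if segments >= best:
            continue
        feasible = True
        inter = rows[0].bits
        for i in range(1, n):
            if cuts >> (i - 1) & 1:
                inter = rows[i].bits
            else:
                inter &= rows[i].bits
                if inter == 0:
                    feasible = False
                    break
        if feasible:
            best = segments
    return best
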