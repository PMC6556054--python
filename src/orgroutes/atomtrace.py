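"""Atom tracking along a route by composition of per-step atom maps.

The quantity of interest is how many heavy atoms of the *start* compound are
still present in the compound at the route frontier.  Tracking keeps, for
each atom of the current compound that originates from the start compound,
the index of its origin atom.  Applying a step composes the step's partial
map with the tracked state, so the set of surviving origins can only shrink.
Atoms introduced by a step (e.g. a sulfate group gained from a co-substrate)
carry no origin and never count as conserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Sequence

from .model import RouteDB, TraversalArc

__all__ = [
    "TrackedAtoms",
    "init_tracking",
    "apply_step",
    "conserved_count",
    "lost_count",
    "track_route",
]


@dataclass(frozen=True)
class TrackedAtoms:
    """Surviving start-compound atoms at the route frontier.

    ``alive`` maps current-compound atom index -> originating start-compound
    atom index.  It is injective by construction (atom maps are injective and
    composition preserves injectivity).
    """

    start_compound_id: str
    current_compound_id: str
    alive: Mapping[int, int]


def init_tracking(db: RouteDB, start_compound_id: str) -> TrackedAtoms:
    """Identity tracking over every heavy atom of the start compound."""
    compound = db.compound(start_compound_id)
    alive = MappingProxyType({i: i for i in range(compound.n_atoms)})
    return TrackedAtoms(start_compound_id, start_compound_id, alive)


def apply_step(tracked: TrackedAtoms, arc: TraversalArc) -> TrackedAtoms:
    """Advance tracking across one arc by composing its atom map.

    The arc must depart from the tracked frontier compound.  The new alive
    set is the relational composition of the arc map with the tracked map;
    its size never increases.
    """
    if arc.from_compound != tracked.current_compound_id:
        raise ValueError(
            f"tracking is at {tracked.current_compound_id!r} but arc departs "
            f"from {arc.from_compound!r}"
        )
    step_map = arc.mapping
    alive = MappingProxyType(
        {
            step_map[i]: origin
            for i, origin in tracked.alive.items()
            if i in step_map
        }
    )
    return TrackedAtoms(tracked.start_compound_id, arc.to_compound, alive)


def conserved_count(tracked: TrackedAtoms) -> int:
    """Number of start-compound atoms still present at the frontier."""
    return len(tracked.alive)


def lost_count(tracked: TrackedAtoms, db: RouteDB) -> int:
    """Number of start-compound atoms no longer present at the frontier."""
    return db.heavy_atom_count(tracked.start_compound_id) - len(tracked.alive)


def track_route(
    db: RouteDB, start_compound_id: str, steps: Sequence[TraversalArc]
) -> TrackedAtoms:
    """Fold :func:`apply_step` over a chain of arcs."""
    tracked = init_tracking(db, start_compound_id)
    for arc in steps:
        tracked = apply_step(tracked, arc)
    return tracked
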