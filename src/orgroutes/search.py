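"""k-best route search minimizing weighted reaction count, atom loss, and
organism switches.

The search is uniform-cost (Dijkstra-style) best-first over partial routes.
A state is a simple path: current compound, surviving start-atom origins,
the running organism set of the switch detector, and the arcs taken.  The
accumulated cost

    w_reaction * steps + w_atom_lost * (start atoms - surviving atoms)
                       + w_switch * switches

is non-negative and non-decreasing under extension (atom loss and greedy
switch count are monotone), so popping partial routes in ascending cost order
is admissible: the first k goal states popped are the k globally cheapest
routes within the length bound.  No heuristic is used; future atom loss has
no admissible estimate without lookahead.

Routes are simple: no repeated compound and no repeated reaction (cycles
cannot lower any cost component).  Ties are broken deterministically by
(cost, step count, lexicographic reaction-id sequence).
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field
from heapq import heappop, heappush
from typing import Callable, Mapping, Sequence

from .atomtrace import track_route
from .errors import OracleBoundError, UnknownIdError
from .model import RouteDB, TraversalArc
from .orgsets import OrgBitset, orgs_for_reaction, union_reactions_for_orgs
from .switchmin import Segment, segment_route

__all__ = [
    "SearchConfig",
    "CostBreakdown",
    "Route",
    "route_cost",
    "search_routes",
    "enumerate_routes_oracle",
]

#: Default weights: one organism switch costs as much as three reaction
#: steps, and a single lost atom costs a tenth of a step, so short,
#: atom-conserving, few-switch routes rank first without small atom
#: differences dominating.
DEFAULT_W_REACTION = 10.0
DEFAULT_W_ATOM_LOST = 1.0
DEFAULT_W_SWITCH = 30.0


@dataclass(frozen=True)
class SearchConfig:
    """Parameters of one route search.

    ``start_set`` / ``goal_set`` are compound ids (a route may run from any
    start to any goal).  ``selected_orgs`` fixes the organism community; only
    reactions present in at least one selected organism are traversable.
    ``excluded_intermediates`` lists compounds that may serve as endpoints
    but never as intermediates (e.g. currency metabolites).
    """

    start_set: tuple[str, ...]
    goal_set: tuple[str, ...]
    selected_orgs: OrgBitset
    w_reaction: float = DEFAULT_W_REACTION
    w_atom_lost: float = DEFAULT_W_ATOM_LOST
    w_switch: float = DEFAULT_W_SWITCH
    k: int = 3
    max_len: int = 6
    time_limit_s: float = 60.0
    excluded_intermediates: tuple[str, ...] = ()
    tie_break: str = "cost-steps-lex"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")
        for name in ("w_reaction", "w_atom_lost", "w_switch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tie_break != "cost-steps-lex":
            raise ValueError(f"unknown tie_break rule {self.tie_break!r}")


@dataclass(frozen=True)
class CostBreakdown:
    """Weighted cost components of a route."""

    reactions: float
    atoms_lost: float
    switches: float

    @property
    def total(self) -> float:
        return self.reactions + self.atoms_lost + self.switches


@dataclass(frozen=True)
class Route:
    """A ranked search result.

    ``segments`` depends on the search mode: with a positive switch cost they
    are the maximal organism segments of the minimum-switch strategy; with
    switch cost zero (minimization off) each step forms its own segment whose
    set is simply the selected organisms containing that reaction.
    ``switches`` is always the minimal (greedy) switch count.
    ``step_orgs`` always holds the per-step selected-organism sets.
    """

    steps: tuple[TraversalArc, ...]
    start_compound: str
    end_compound: str
    conserved_atoms: int
    atoms_lost: int
    switches: int
    segments: tuple[Segment, ...]
    step_orgs: tuple[OrgBitset, ...]
    cost: CostBreakdown
    switch_minimized: bool = True

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(arc.reaction_id for arc in self.steps)

    @property
    def compound_chain(self) -> tuple[str, ...]:
        return (self.start_compound,) + tuple(arc.to_compound for arc in self.steps)


def route_cost(route: Route, config: SearchConfig) -> CostBreakdown:
    """Pure recomputation of the weighted cost of a route."""
    return CostBreakdown(
        reactions=config.w_reaction * len(route.steps),
        atoms_lost=config.w_atom_lost * route.atoms_lost,
        switches=config.w_switch * route.switches,
    )


def _build_route(
    db: RouteDB,
    config: SearchConfig,
    start: str,
    steps: Sequence[TraversalArc],
) -> Route:
    """Assemble a Route from a chain of arcs: compose atom maps, segment the
    reaction sequence, and attach the cost breakdown."""
    steps = tuple(steps)
    tracked = track_route(db, start, steps)
    conserved = len(tracked.alive)
    atoms_lost = db.heavy_atom_count(start) - conserved
    matrix = db.org_matrix
    rids = tuple(arc.reaction_id for arc in steps)
    step_orgs = tuple(
        orgs_for_reaction(matrix, rid, config.selected_orgs) for rid in rids
    )
    if steps:
        switches, greedy_segments = segment_route(matrix, config.selected_orgs, rids)
    else:
        switches, greedy_segments = 0, ()
    minimized = config.w_switch > 0
    if minimized or not steps:
        segments = greedy_segments
    else:
        segments = tuple(Segment(orgs, (rid,)) for orgs, rid in zip(step_orgs, rids))
    cost = CostBreakdown(
        reactions=config.w_reaction * len(steps),
        atoms_lost=config.w_atom_lost * atoms_lost,
        switches=config.w_switch * switches,
    )
    return Route(
        steps=steps,
        start_compound=start,
        end_compound=tracked.current_compound_id,
        conserved_atoms=conserved,
        atoms_lost=atoms_lost,
        switches=switches,
        segments=segments,
        step_orgs=step_orgs,
        cost=cost,
        switch_minimized=minimized,
    )


def _resolve_endpoints(db: RouteDB, config: SearchConfig) -> tuple[set[str], set[str]]:
    if not config.start_set:
        raise ValueError("start set is empty")
    if not config.goal_set:
        raise ValueError("goal set is empty")
    for cid in (*config.start_set, *config.goal_set):
        db.compound(cid)  # raises UnknownIdError
    return set(config.start_set), set(config.goal_set)


def _allowed_arcs_by_from(
    db: RouteDB, config: SearchConfig
) -> dict[str, tuple[TraversalArc, ...]]:
    allowed = union_reactions_for_orgs(db.org_matrix, config.selected_orgs)
    return {
        cid: tuple(a for a in arcs if a.reaction_id in allowed)
        for cid, arcs in db.arcs_by_from.items()
    }


@dataclass
class _PathState:
    start: str
    current: str
    alive: Mapping[int, int]
    visited: frozenset[str]
    used_reactions: frozenset[str]
    steps: tuple[TraversalArc, ...]
    S: OrgBitset | None
    switches: int


def search_routes(
    db: RouteDB,
    config: SearchConfig,
    *,
    clock: Callable[[], float] = time.monotonic,
) -> tuple[list[Route], str]:
    """Find up to ``config.k`` cheapest simple routes from any start to any
    goal compound within the selected community.

    Returns ``(routes, status)`` with ``status`` either ``"complete"`` (the
    returned costs are globally optimal among routes of length <= max_len) or
    ``"timeout"`` (the wall-clock budget expired; best routes found so far
    are returned).  A start compound that is also a goal yields a zero-step
    route of cost 0.
    """
    starts, goals = _resolve_endpoints(db, config)
    arcs_by_from = _allowed_arcs_by_from(db, config)
    excluded = set(config.excluded_intermediates)
    matrix = db.org_matrix

    heap: list = []
    counter = itertools.count()
    for start in sorted(starts):
        n = db.heavy_atom_count(start)
        state = _PathState(
            start=start,
            current=start,
            alive={i: i for i in range(n)},
            visited=frozenset({start}),
            used_reactions=frozenset(),
            steps=(),
            S=None,
            switches=0,
        )
        heappush(heap, (0.0, 0, (), next(counter), state))

    routes: list[Route] = []
    status = "complete"
    t0 = clock()
    while heap:
        if clock() - t0 > config.time_limit_s:
            status = "timeout"
            break
        cost, n_steps, rids, _, st = heappop(heap)
        if st.current in goals:
            routes.append(_build_route(db, config, st.start, st.steps))
            if len(routes) >= config.k:
                break
        if n_steps >= config.max_len:
            continue
        if st.current in excluded and st.current != st.start:
            continue  # excluded compounds terminate paths, they never relay
        start_atoms = db.heavy_atom_count(st.start)
        for arc in arcs_by_from.get(st.current, ()):
            if arc.reaction_id in st.used_reactions or arc.to_compound in st.visited:
                continue
            if arc.to_compound in excluded and arc.to_compound not in goals:
                continue
            step_map = arc.mapping
            new_alive = {
                step_map[i]: origin
                for i, origin in st.alive.items()
                if i in step_map
            }
            row = orgs_for_reaction(matrix, arc.reaction_id, config.selected_orgs)
            if st.S is None:
                new_S, new_switches = row, 0
            else:
                inter = st.S & row
                if inter.is_empty():
                    new_S, new_switches = row, st.switches + 1
                else:
                    new_S, new_switches = inter, st.switches
            new_steps = st.steps + (arc,)
            new_rids = rids + (arc.reaction_id,)
            new_cost = (
                config.w_reaction * (n_steps + 1)
                + config.w_atom_lost * (start_atoms - len(new_alive))
                + config.w_switch * new_switches
            )
            new_state = _PathState(
                start=st.start,
                current=arc.to_compound,
                alive=new_alive,
                visited=st.visited | {arc.to_compound},
                used_reactions=st.used_reactions | {arc.reaction_id},
                steps=new_steps,
                S=new_S,
                switches=new_switches,
            )
            heappush(heap, (new_cost, n_steps + 1, new_rids, next(counter), new_state))
    return routes, status


def enumerate_routes_oracle(
    db: RouteDB,
    config: SearchConfig,
    *,
    path_budget: int = 500_000,
) -> list[Route]:
    """Exhaustive DFS enumeration of every simple route from the start set to
    the goal set within ``max_len``, globally ranked.

    Independent of the best-first search machinery: a brute-force ranking
    oracle for small networks.  Raises :class:`OracleBoundError` if more than
    ``path_budget`` partial paths are visited.
    """
    starts, goals = _resolve_endpoints(db, config)
    arcs_by_from = _allowed_arcs_by_from(db, config)
    excluded = set(config.excluded_intermediates)
    found: list[tuple[str, tuple[TraversalArc, ...]]] = []
    visited_paths = 0

    def dfs(
        start: str,
        current: str,
        visited: set[str],
        used: set[str],
        steps: list[TraversalArc],
    ) -> None:
        nonlocal visited_paths
        visited_paths += 1
        if visited_paths > path_budget:
            raise OracleBoundError(
                f"oracle exceeded its budget of {path_budget} partial paths"
            )
        if current in goals:
            found.append((start, tuple(steps)))
        if len(steps) >= config.max_len:
            return
        if current in excluded and current != start:
            return
        for arc in arcs_by_from.get(current, ()):
            if arc.reaction_id in used or arc.to_compound in visited:
                continue
            if arc.to_compound in excluded and arc.to_compound not in goals:
                continue
            visited.add(arc.to_compound)
            used.add(arc.reaction_id)
            steps.append(arc)
            dfs(start, arc.to_compound, visited, used, steps)
            steps.pop()
            used.discard(arc.reaction_id)
            visited.discard(arc.to_compound)

    for start in sorted(starts):
        dfs(start, start, {start}, set(), [])

    routes = [_build_route(db, config, start, steps) for start, steps in found]
    routes.sort(key=lambda r: (r.cost.total, len(r.steps), r.reaction_ids))
    return routes
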