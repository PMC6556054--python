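"""Domain model: compounds, reactions, atom mappings, and the assembled
reaction-network database.

Compounds carry an ordered list of heavy (non-hydrogen) atoms; hydrogens are
excluded throughout, which is standard atom-mapping practice.  An atom map is
a partial injective correspondence between the heavy atoms of one substrate
and one product of a reaction.  From the validated tables the database
derives *traversal arcs*: one directed (substrate -> product) edge per mapped
compound pair, the unit of movement during route search.  Reversible
reactions additionally contribute the reverse arc with the inverted map.

Side (unmapped) substrates and products exist in the reaction tables but are
ignored by traversal: a route step is a single substrate-to-product arc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import UnknownIdError, ValidationError
from .orgsets import OrganismMatrix

__all__ = [
    "Compound",
    "Reaction",
    "AtomMap",
    "TraversalArc",
    "RouteDB",
    "build_db",
    "arcs_of_reaction",
]


@dataclass(frozen=True)
class Compound:
    """A metabolite with its ordered heavy-atom element list.

    Atom indices used in atom maps are 0-based positions into ``atoms``; the
    order given at construction is part of the file contract.
    """

    id: str
    name: str
    atoms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValidationError(f"compound {self.id!r} has an empty atom list")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass(frozen=True)
class Reaction:
    """A reaction as written: substrate ids, product ids, reversibility flag.

    Reactions default to irreversible; reversibility is an explicit input
    flag, never inferred.
    """

    id: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    reversible: bool = False

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise ValidationError(
                f"reaction {self.id!r} must have non-empty substrate and product lists"
            )


@dataclass(frozen=True)
class AtomMap:
    """Partial injective map between heavy atoms of one (substrate, product)
    pair of a reaction; ``pairs`` holds (substrate_index, product_index)."""

    reaction_id: str
    substrate_id: str
    product_id: str
    pairs: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class TraversalArc:
    """One traversable edge: a reaction moving material from one compound to
    another under a specific atom map.

    ``pairs`` maps from-compound atom indices to to-compound atom indices.
    ``forward`` is False for the reverse arc of a reversible reaction.
    """

    reaction_id: str
    from_compound: str
    to_compound: str
    pairs: tuple[tuple[int, int], ...]
    forward: bool = True

    @property
    def mapping(self) -> dict[int, int]:
        return dict(self.pairs)

    def inverted(self) -> "TraversalArc":
        inv = tuple(sorted((j, i) for i, j in self.pairs))
        return TraversalArc(
            self.reaction_id, self.to_compound, self.from_compound, inv, not self.forward
        )


@dataclass(frozen=True, eq=False)
class RouteDB:
    """The assembled, validated network: compounds, reactions, atom maps,
    organism presence matrix, and derived traversal arcs.

    Instances are immutable values produced by :func:`build_db`.
    """

    compounds: Mapping[str, Compound]
    reactions: Mapping[str, Reaction]
    atom_maps: Mapping[tuple[str, str, str], AtomMap]
    org_matrix: OrganismMatrix
    arcs: tuple[TraversalArc, ...]
    arcs_by_from: Mapping[str, tuple[TraversalArc, ...]]

    def compound(self, compound_id: str) -> Compound:
        try:
            return self.compounds[compound_id]
        except KeyError:
            raise UnknownIdError(f"unknown compound id {compound_id!r}") from None

    def reaction(self, reaction_id: str) -> Reaction:
        try:
            return self.reactions[reaction_id]
        except KeyError:
            raise UnknownIdError(f"unknown reaction id {reaction_id!r}") from None

    def heavy_atom_count(self, compound_id: str) -> int:
        return self.compound(compound_id).n_atoms

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RouteDB):
            return NotImplemented
        return (
            dict(self.compounds) == dict(other.compounds)
            and dict(self.reactions) == dict(other.reactions)
            and dict(self.atom_maps) == dict(other.atom_maps)
            and self.org_matrix == other.org_matrix
            and set(self.arcs) == set(other.arcs)
        )


def _validate_atom_map(
    amap: AtomMap,
    reactions: Mapping[str, Reaction],
    compounds: Mapping[str, Compound],
) -> None:
    rid = amap.reaction_id
    if rid not in reactions:
        raise ValidationError(f"atom map references unknown reaction {rid!r}")
    rxn = reactions[rid]
    if amap.substrate_id not in rxn.substrates:
        raise ValidationError(
            f"atom map for {rid!r}: {amap.substrate_id!r} is not a substrate"
        )
    if amap.product_id not in rxn.products:
        raise ValidationError(
            f"atom map for {rid!r}: {amap.product_id!r} is not a product"
        )
    sub = compounds[amap.substrate_id]
    prod = compounds[amap.product_id]
    seen_sub: set[int] = set()
    seen_prod: set[int] = set()
    for i, j in amap.pairs:
        if not 0 <= i < sub.n_atoms:
            raise ValidationError(
                f"atom map for {rid!r}: substrate index {i} out of range "
                f"for {sub.id!r} ({sub.n_atoms} atoms)"
            )
        if not 0 <= j < prod.n_atoms:
            raise ValidationError(
                f"atom map for {rid!r}: product index {j} out of range "
                f"for {prod.id!r} ({prod.n_atoms} atoms)"
            )
        if i in seen_sub or j in seen_prod:
            raise ValidationError(
                f"atom map for {rid!r} pair ({i}, {j}) violates injectivity"
            )
        seen_sub.add(i)
        seen_prod.add(j)
        if sub.atoms[i] != prod.atoms[j]:
            raise ValidationError(
                f"atom map for {rid!r} pair ({i}, {j}) crosses elements: "
                f"{sub.atoms[i]} vs {prod.atoms[j]}"
            )


def build_db(
    compounds: Iterable[Compound],
    reactions: Iterable[Reaction],
    atom_maps: Iterable[AtomMap],
    org_matrix: OrganismMatrix,
) -> RouteDB:
    """Assemble and cross-validate a :class:`RouteDB`.

    Validates id uniqueness, dangling references, atom-map injectivity and
    element consistency, and that every reaction with an organism row exists.
    Derived arcs are computed deterministically: reactions in input order,
    atom maps per reaction in (substrate, product) order, the reverse arc of
    a reversible reaction immediately after its forward arc.
    """
    cmap: dict[str, Compound] = {}
    for c in compounds:
        if c.id in cmap:
            raise ValidationError(f"duplicate compound id {c.id!r}")
        cmap[c.id] = c

    rmap: dict[str, Reaction] = {}
    for r in reactions:
        if r.id in rmap:
            raise ValidationError(f"duplicate reaction id {r.id!r}")
        for cid in (*r.substrates, *r.products):
            if cid not in cmap:
                raise ValidationError(
                    f"reaction {r.id!r} references unknown compound {cid!r}"
                )
        rmap[r.id] = r

    amaps: dict[tuple[str, str, str], AtomMap] = {}
    for am in atom_maps:
        _validate_atom_map(am, rmap, cmap)
        key = (am.reaction_id, am.substrate_id, am.product_id)
        if key in amaps:
            raise ValidationError(f"duplicate atom map for {key!r}")
        amaps[key] = am

    for rid in org_matrix.reaction_ids:
        if rid not in rmap:
            raise ValidationError(
                f"organism matrix row references unknown reaction {rid!r}"
            )

    arcs: list[TraversalArc] = []
    for rid, rxn in rmap.items():
        keys = sorted(k for k in amaps if k[0] == rid)
        for key in keys:
            am = amaps[key]
            if not am.pairs:
                continue
            fwd = TraversalArc(
                rid, am.substrate_id, am.product_id, tuple(sorted(am.pairs))
            )
            arcs.append(fwd)
            if rxn.reversible:
                arcs.append(fwd.inverted())

    by_from: dict[str, list[TraversalArc]] = {}
    for arc in arcs:
        by_from.setdefault(arc.from_compound, []).append(arc)
    arcs_by_from = {
        cid: tuple(sorted(v, key=lambda a: (a.reaction_id, a.to_compound, not a.forward)))
        for cid, v in by_from.items()
    }

    return RouteDB(
        compounds=cmap,
        reactions=rmap,
        atom_maps=amaps,
        org_matrix=org_matrix,
        arcs=tuple(arcs),
        arcs_by_from=arcs_by_from,
    )


def arcs_of_reaction(db: RouteDB, reaction_id: str) -> list[TraversalArc]:
    """All traversal arcs contributed by one reaction (forward and, for
    reversible reactions, reverse)."""
    db.reaction(reaction_id)  # raises UnknownIdError if absent
    return [a for a in db.arcs if a.reaction_id == reaction_id]
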