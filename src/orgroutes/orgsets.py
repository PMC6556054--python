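"""Organism bit sets and the reaction-by-organism presence matrix.

A community search needs two fast queries: "which selected organisms contain
reaction R?" and "which reactions exist anywhere in the selected community?".
Both are answered from a binary presence matrix whose rows are reaction
identifiers and whose columns are organisms.  Organism sets are dense
fixed-width bit vectors (one bit per organism in a frozen universe), so
intersection, union and emptiness tests are single integer operations; a
sparse representation is deliberately not offered because typical reactions
occur in many organisms, which makes the rows dense in practice.

Organism column indices are assigned by input order when the matrix is built
and are frozen afterwards; every :class:`OrgBitset` carries its universe size
and refuses operations across mismatched universes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import EmptySelectionError, UniverseMismatchError, ValidationError

__all__ = [
    "Organism",
    "OrgBitset",
    "OrganismMatrix",
    "select_organisms",
    "orgs_for_reaction",
    "union_reactions_for_orgs",
    "summarize_by_tag",
]


@dataclass(frozen=True)
class Organism:
    """One organism column: identifier, display name, free-form metadata tags
    (e.g. body-site names)."""

    id: str
    name: str
    tags: tuple[str, ...] = ()


@dataclass(frozen=True)
class OrgBitset:
    """Immutable fixed-width bit set over an organism universe.

    ``bits`` is an arbitrary-precision integer interpreted as a bit vector:
    bit ``i`` set means organism at column ``i`` is a member.
    """

    universe_size: int
    bits: int = 0

    def __post_init__(self) -> None:
        if self.universe_size < 0:
            raise ValueError("universe_size must be non-negative")
        if self.bits < 0 or self.bits >> self.universe_size:
            raise ValueError("bits fall outside the organism universe")

    # -- constructors ------------------------------------------------------
    @classmethod
    def empty(cls, universe_size: int) -> "OrgBitset":
        return cls(universe_size, 0)

    @classmethod
    def full(cls, universe_size: int) -> "OrgBitset":
        return cls(universe_size, (1 << universe_size) - 1)

    @classmethod
    def from_indices(cls, universe_size: int, indices: Iterable[int]) -> "OrgBitset":
        bits = 0
        for i in indices:
            if not 0 <= i < universe_size:
                raise ValueError(f"organism index {i} outside universe of {universe_size}")
            bits |= 1 << i
        return cls(universe_size, bits)

    # -- algebra -----------------------------------------------------------
    def _check(self, other: "OrgBitset") -> None:
        if not isinstance(other, OrgBitset):
            raise TypeError("expected an OrgBitset operand")
        if other.universe_size != self.universe_size:
            raise UniverseMismatchError(
                f"universe sizes differ: {self.universe_size} vs {other.universe_size}"
            )

    def __and__(self, other: "OrgBitset") -> "OrgBitset":
        self._check(other)
        return OrgBitset(self.universe_size, self.bits & other.bits)

    def __or__(self, other: "OrgBitset") -> "OrgBitset":
        self._check(other)
        return OrgBitset(self.universe_size, self.bits | other.bits)

    def complement(self) -> "OrgBitset":
        return OrgBitset(self.universe_size, self.bits ^ ((1 << self.universe_size) - 1))

    def is_empty(self) -> bool:
        return self.bits == 0

    def popcount(self) -> int:
        return self.bits.bit_count()

    def __len__(self) -> int:
        return self.popcount()

    def __contains__(self, index: int) -> bool:
        return 0 <= index < self.universe_size and bool(self.bits >> index & 1)

    def indices(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.universe_size) if self.bits >> i & 1)

    def issubset(self, other: "OrgBitset") -> bool:
        self._check(other)
        return self.bits & ~other.bits == 0


class OrganismMatrix:
    """Reaction-by-organism binary presence matrix over a frozen universe.

    Only rows with at least one set bit are stored; looking up an absent
    reaction yields the empty set.  The matrix is immutable after
    construction.
    """

    def __init__(self, organisms: Sequence[Organism], rows: Mapping[str, OrgBitset]):
        self._organisms = tuple(organisms)
        seen: set[str] = set()
        for org in self._organisms:
            if org.id in seen:
                raise ValidationError(f"duplicate organism id {org.id!r}")
            seen.add(org.id)
        self._position = {org.id: i for i, org in enumerate(self._organisms)}
        n = len(self._organisms)
        stored: dict[str, OrgBitset] = {}
        for rid, row in rows.items():
            if row.universe_size != n:
                raise UniverseMismatchError(
                    f"row for reaction {rid!r} has universe {row.universe_size}, matrix has {n}"
                )
            if not row.is_empty():
                stored[rid] = row
        self._rows = stored

    @classmethod
    def from_membership(
        cls,
        organisms: Sequence[Organism],
        membership: Mapping[str, Sequence[str]],
    ) -> "OrganismMatrix":
        """Build from sparse (reaction id -> organism ids) membership lists."""
        position = {org.id: i for i, org in enumerate(organisms)}
        n = len(organisms)
        rows: dict[str, OrgBitset] = {}
        for rid, org_ids in membership.items():
            bits = 0
            for oid in org_ids:
                if oid not in position:
                    raise ValidationError(
                        f"reaction {rid!r} references unknown organism {oid!r}"
                    )
                bits |= 1 << position[oid]
            rows[rid] = OrgBitset(n, bits)
        return cls(organisms, rows)

    # -- read-only views ---------------------------------------------------
    @property
    def organisms(self) -> tuple[Organism, ...]:
        return self._organisms

    @property
    def universe_size(self) -> int:
        return len(self._organisms)

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self._rows))

    def position(self, org_id: str) -> int:
        return self._position[org_id]

    def organism_at(self, index: int) -> Organism:
        return self._organisms[index]

    def row(self, reaction_id: str) -> OrgBitset:
        """Organisms containing the reaction; all-zero for an absent row."""
        return self._rows.get(reaction_id, OrgBitset.empty(self.universe_size))

    def has_row(self, reaction_id: str) -> bool:
        return reaction_id in self._rows

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OrganismMatrix):
            return NotImplemented
        return self._organisms == other._organisms and self._rows == other._rows

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"OrganismMatrix({self.universe_size} organisms, "
            f"{len(self._rows)} non-empty reaction rows)"
        )


def select_organisms(matrix: OrganismMatrix, query: Sequence[str]) -> OrgBitset:
    """Select organisms by a union of query terms.

    Each term matches organisms by exact id, by case-insensitive substring of
    the display name, or by case-insensitive exact tag (e.g. a body-site
    name).  The result is the union over all terms.

    Raises :class:`EmptySelectionError` if nothing matches: a route search
    over an empty community would be vacuous.
    """
    if not query:
        raise EmptySelectionError("organism query is empty")
    bits = 0
    for term in query:
        low = term.lower()
        for i, org in enumerate(matrix.organisms):
            if (
                term == org.id
                or low in org.name.lower()
                or any(low == tag.lower() for tag in org.tags)
            ):
                bits |= 1 << i
    if bits == 0:
        raise EmptySelectionError(f"no organism matches query {list(query)!r}")
    return OrgBitset(matrix.universe_size, bits)


def orgs_for_reaction(
    matrix: OrganismMatrix, reaction_id: str, selected: OrgBitset
) -> OrgBitset:
    """Selected organisms that contain the reaction (row AND selection)."""
    return matrix.row(reaction_id) & selected


def union_reactions_for_orgs(
    matrix: OrganismMatrix, selected: OrgBitset
) -> frozenset[str]:
    """All reaction ids present in at least one selected organism.

    This union defines the searchable reaction universe for a community.
    """
    selected._check(OrgBitset.empty(matrix.universe_size))
    return frozenset(
        rid for rid in matrix._rows if matrix._rows[rid].bits & selected.bits
    )


def summarize_by_tag(matrix: OrganismMatrix) -> pd.DataFrame:
    """Per-tag community capability summary.

    One row per distinct tag with the organism count and the size of the
    union of reactions over the tag's members, plus a grand-total row
    (tag ``"(total)"``) computed as the union over all tagged organisms.
    """
    tags = sorted({tag for org in matrix.organisms for tag in org.tags})
    records = []
    all_tagged = 0
    for tag in tags:
        bits = 0
        for i, org in enumerate(matrix.organisms):
            if tag in org.tags:
                bits |= 1 << i
        all_tagged |= bits
        sel = OrgBitset(matrix.universe_size, bits)
        records.append(
            {
                "tag": tag,
                "organisms": sel.popcount(),
                "reactions": len(union_reactions_for_orgs(matrix, sel)),
            }
        )
    total_sel = OrgBitset(matrix.universe_size, all_tagged)
    records.append(
        {
            "tag": "(total)",
            "organisms": total_sel.popcount(),
            "reactions": len(union_reactions_for_orgs(matrix, total_sel)),
        }
    )
    return pd.DataFrame.from_records(records, columns=["tag", "organisms", "reactions"])
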