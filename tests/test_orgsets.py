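"""Bit-set algebra, organism selection, and presence-matrix queries checked
against naive list-of-ids oracles."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

import orgroutes as orr
from orgroutes.orgsets import (
    Organism,
    OrganismMatrix,
    OrgBitset,
    orgs_for_reaction,
    select_organisms,
    summarize_by_tag,
    union_reactions_for_orgs,
)

UNIVERSE = 24
subsets = st.sets(st.integers(min_value=0, max_value=UNIVERSE - 1))


def bs(idxs):
    return OrgBitset.from_indices(UNIVERSE, idxs)


class TestBitsetAlgebra:
    @given(subsets, subsets, subsets)
    def test_set_laws(self, a, b, c):
        A, B, C = bs(a), bs(b), bs(c)
        assert A & B == B & A
        assert A | B == B | A
        assert (A & B) & C == A & (B & C)
        assert A & A == A
        assert set((A & B).indices()) == a & b
        assert set((A | B).indices()) == a | b
        # De Morgan within the universe
        assert (A & B).complement() == A.complement() | B.complement()

    @given(subsets)
    def test_popcount_emptiness_and_double_complement(self, a):
        A = bs(a)
        assert A.popcount() == len(a)
        assert A.is_empty() == (len(a) == 0)
        assert A.complement().complement() == A

    def test_mismatched_universes_refused(self):
        with pytest.raises(orr.UniverseMismatchError):
            OrgBitset.from_indices(4, [1]) & OrgBitset.from_indices(5, [1])

    def test_bits_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            OrgBitset(3, 0b1000)


def random_matrix(seed, n_orgs=20, n_reactions=30, n_tags=3):
    rng = random.Random(seed)
    orgs = [
        Organism(
            f"ORG-{i:02d}",
            f"organism number {i}",
            tuple(sorted(rng.sample([f"TAG-{t}" for t in range(n_tags)], rng.randint(1, 2)))),
        )
        for i in range(n_orgs)
    ]
    membership = {}
    for r in range(n_reactions):
        members = [o.id for o in orgs if rng.random() < rng.uniform(0.1, 0.8)]
        if members:
            membership[f"RXN-{r:02d}"] = members
    return OrganismMatrix.from_membership(orgs, membership), membership


class TestSelection:
    def test_gi_human_selection_on_trp_fixture(self, trp_db, trp_selection):
        matrix = trp_db.org_matrix
        ids = {matrix.organism_at(i).id for i in trp_selection.indices()}
        assert ids == {"GUT-1", "GUT-2", "GUT-3", "GUT-4", "GUT-5", "HUMAN"}
        assert "SKIN-1" not in ids

    def test_all_ids_select_full_universe(self, trp_db):
        matrix = trp_db.org_matrix
        sel = select_organisms(matrix, [o.id for o in matrix.organisms])
        assert sel == OrgBitset.full(matrix.universe_size)

    def test_union_of_overlapping_tag_queries_matches_list_oracle(self):
        matrix, _ = random_matrix(5)
        sel = select_organisms(matrix, ["TAG-0", "TAG-1"])
        naive = {o.id for o in matrix.organisms if {"TAG-0", "TAG-1"} & set(o.tags)}
        assert sel.popcount() == len(naive)

    def test_empty_selection_is_an_error(self, trp_db):
        with pytest.raises(orr.EmptySelectionError):
            select_organisms(trp_db.org_matrix, ["no-such-organism-anywhere"])
        with pytest.raises(orr.EmptySelectionError):
            select_organisms(trp_db.org_matrix, [])


class TestMatrixQueries:
    def test_human_only_step_intersection(self, trp_db, trp_selection):
        matrix = trp_db.org_matrix
        row = orgs_for_reaction(matrix, "RXN-IND-SULFO", trp_selection)
        assert row.popcount() == 1
        assert matrix.organism_at(row.indices()[0]).id == "HUMAN"

    def test_empty_selection_absorbs(self, trp_db):
        matrix = trp_db.org_matrix
        empty = OrgBitset.empty(matrix.universe_size)
        assert orgs_for_reaction(matrix, "RXN-TNASE-A", empty).is_empty()
        assert union_reactions_for_orgs(matrix, empty) == frozenset()

    def test_missing_row_yields_empty_set(self, trp_db):
        matrix = trp_db.org_matrix
        full = OrgBitset.full(matrix.universe_size)
        assert orgs_for_reaction(matrix, "RXN-NOT-THERE", full).is_empty()

    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_row_and_union_match_list_oracle(self, seed):
        matrix, membership = random_matrix(seed)
        full = OrgBitset.full(matrix.universe_size)
        for rid, members in membership.items():
            got = orgs_for_reaction(matrix, rid, full)
            assert {matrix.organism_at(i).id for i in got.indices()} == set(members)
        for org in matrix.organisms:
            single = select_organisms(matrix, [org.id])
            naive = {rid for rid, members in membership.items() if org.id in members}
            assert union_reactions_for_orgs(matrix, single) == naive

    @given(subsets, subsets)
    def test_union_reactions_monotone_in_selection(self, a, b):
        matrix, _ = random_matrix(11, n_orgs=UNIVERSE)
        small = OrgBitset.from_indices(matrix.universe_size, a)
        large = small | OrgBitset.from_indices(matrix.universe_size, b)
        assert union_reactions_for_orgs(matrix, small) <= union_reactions_for_orgs(
            matrix, large
        )


class TestSummarize:
    def test_per_tag_counts_match_naive_recomputation(self):
        matrix, membership = random_matrix(11, n_tags=3)
        table = summarize_by_tag(matrix).set_index("tag")
        for tag in ("TAG-0", "TAG-1", "TAG-2"):
            members = {o.id for o in matrix.organisms if tag in o.tags}
            union = {rid for rid, ms in membership.items() if members & set(ms)}
            assert table.loc[tag, "organisms"] == len(members)
            assert table.loc[tag, "reactions"] == len(union)

    def test_total_row_is_union_not_sum(self, trp_db):
        table = summarize_by_tag(trp_db.org_matrix).set_index("tag")
        per_tag_sum = int(table.drop(index="(total)")["organisms"].sum())
        assert table.loc["(total)", "organisms"] <= per_tag_sum
        assert table.loc["(total)", "organisms"] == trp_db.org_matrix.universe_size

    def test_single_tag_matrix(self):
        orgs = [Organism("O1", "one", ("gut",)), Organism("O2", "two", ("gut",))]
        matrix = OrganismMatrix.from_membership(orgs, {"R1": ["O1"], "R2": ["O1", "O2"]})
        table = summarize_by_tag(matrix).set_index("tag")
        assert table.loc["gut", "organisms"] == 2
        assert table.loc["gut", "reactions"] == 2
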