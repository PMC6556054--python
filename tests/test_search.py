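"""Best-first k-route search: golden fixture behavior, oracle equivalence on
random networks, weight monotonicity, tie-break determinism, timeout."""

import pytest

import orgroutes as orr
from orgroutes.orgsets import OrgBitset
from orgroutes.search import SearchConfig, enumerate_routes_oracle, route_cost, search_routes

from conftest import gi_human_config


def full_config(db, starts, goals, **kw):
    return SearchConfig(
        tuple(starts), tuple(goals), OrgBitset.full(db.org_matrix.universe_size), **kw
    )


class TestRouteCost:
    def test_trp_best_route_cost_breakdown(self, trp_routes):
        best = trp_routes[0]
        assert (best.cost.reactions, best.cost.atoms_lost, best.cost.switches) == (
            30.0,
            6.0,
            30.0,
        )
        assert best.cost.total == 66.0

    def test_cost_is_pure_recomputation(self, trp_db, trp_routes):
        cfg = gi_human_config(trp_db, ["L-TRYPTOPHAN"], ["INDOXYL-SULFATE"])
        for route in trp_routes:
            assert route_cost(route, cfg) == route.cost

    def test_all_zero_weights_give_zero_cost(self, trp_db):
        cfg = gi_human_config(
            trp_db,
            ["L-TRYPTOPHAN"],
            ["INDOXYL-SULFATE"],
            w_reaction=0,
            w_atom_lost=0,
            w_switch=0,
            k=1,
            max_len=9,
        )
        routes, _ = search_routes(trp_db, cfg)
        assert routes[0].cost.total == 0.0

    def test_ahl_switch_component_is_zero(self, ahl_routes):
        assert all(r.cost.switches == 0.0 for r in ahl_routes)

    def test_invalid_config_rejected(self, trp_db, trp_selection):
        with pytest.raises(ValueError):
            SearchConfig(("A",), ("B",), trp_selection, k=0)
        with pytest.raises(ValueError):
            SearchConfig(("A",), ("B",), trp_selection, w_switch=-1)


class TestFixtureSearches:
    def test_trp_top_routes(self, trp_routes):
        best = trp_routes[0]
        assert best.reaction_ids == (
            "RXN-TNASE-A",
            "RXN-IND-MONOOX",
            "RXN-IND-SULFO",
        )
        assert (len(best.steps), best.conserved_atoms, best.switches) == (3, 9, 1)
        # top two differ only in the first reaction
        assert trp_routes[0].steps[0] != trp_routes[1].steps[0]
        assert trp_routes[0].steps[1:] == trp_routes[1].steps[1:]

    def test_unreachable_goal_returns_empty_complete(self, trp_db):
        cfg = gi_human_config(trp_db, ["INDOXYL-SULFATE"], ["L-TRYPTOPHAN"], max_len=9)
        routes, status = search_routes(trp_db, cfg)
        assert routes == [] and status == "complete"

    def test_start_equals_goal_yields_zero_step_route(self, trp_db):
        cfg = gi_human_config(trp_db, ["INDOLE"], ["INDOLE"], k=1)
        routes, status = search_routes(trp_db, cfg)
        assert status == "complete"
        assert routes[0].steps == () and routes[0].cost.total == 0.0

    def test_empty_endpoint_sets_rejected(self, trp_db, trp_selection):
        cfg = SearchConfig((), ("INDOLE",), trp_selection)
        with pytest.raises(ValueError):
            search_routes(trp_db, cfg)

    def test_unknown_endpoint_rejected(self, trp_db, trp_selection):
        cfg = SearchConfig(("NOPE",), ("INDOLE",), trp_selection)
        with pytest.raises(orr.UnknownIdError):
            search_routes(trp_db, cfg)

    def test_selection_restricts_reaction_universe(self, trp_db):
        # with only the human host selected, the microbial first step is
        # unavailable and no route exists
        human_only = orr.select_organisms(trp_db.org_matrix, ["Homo sapiens"])
        cfg = SearchConfig(
            ("L-TRYPTOPHAN",), ("INDOXYL-SULFATE",), human_only, k=3, max_len=9
        )
        routes, status = search_routes(trp_db, cfg)
        assert routes == [] and status == "complete"

    def test_excluded_intermediate_forces_detour_or_kills_route(self, trp_db):
        cfg = gi_human_config(
            trp_db,
            ["L-TRYPTOPHAN"],
            ["INDOXYL-SULFATE"],
            k=5,
            max_len=9,
            excluded_intermediates=("INDOLE",),
        )
        routes, _ = search_routes(trp_db, cfg)
        assert routes
        assert all("INDOLE" not in r.compound_chain for r in routes)

    def test_zero_time_limit_times_out(self, trp_db):
        cfg = gi_human_config(
            trp_db, ["L-TRYPTOPHAN"], ["INDOXYL-SULFATE"], time_limit_s=0.0
        )
        routes, status = search_routes(trp_db, cfg)
        assert status == "timeout"
        assert routes == []


class TestSwitchCostSensitivity:
    def test_zero_switch_cost_exposes_degrade_only_organism(self, ahl_db):
        matrix = ahl_db.org_matrix
        base = dict(k=4, max_len=4)
        with_cost = gi_human_config(
            ahl_db, ["S-ADENOSYLMETHIONINE"], ["L-HOMOSERINE-LACTONE"], **base
        )
        no_cost = gi_human_config(
            ahl_db,
            ["S-ADENOSYLMETHIONINE"],
            ["L-HOMOSERINE-LACTONE"],
            w_switch=0,
            **base,
        )
        ralsto = matrix.position("RALSTO")

        routes_w, _ = search_routes(ahl_db, with_cost)
        for route in routes_w:
            assert route.switch_minimized
            step2_orgs = route.segments[-1].organisms
            assert ralsto not in step2_orgs  # minimum-switch strategy excludes it

        routes_0, _ = search_routes(ahl_db, no_cost)
        assert {r.reaction_ids for r in routes_0} == {
            r.reaction_ids for r in routes_w
        }  # ranking unchanged, only annotation differs
        for route in routes_0:
            assert not route.switch_minimized
            step2_orgs = route.segments[1].organisms
            assert ralsto in step2_orgs

    def test_pseudomonas_analog_spans_both_steps(self, ahl_db, ahl_routes):
        pseudo = ahl_db.org_matrix.position("PSEUDO")
        for route in ahl_routes:
            assert all(pseudo in orgs for orgs in route.step_orgs)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_search_matches_exhaustive_oracle(self, seed):
        db = orr.gen_random_network(seed, n_compounds=12, n_reactions=18, n_orgs=8)
        cids = sorted(db.compounds)
        cfg = full_config(db, [cids[0], cids[1]], [cids[-1], cids[-2]], k=5, max_len=5)
        routes, status = search_routes(db, cfg)
        assert status == "complete"
        oracle = enumerate_routes_oracle(db, cfg)
        assert [r.cost.total for r in routes] == [o.cost.total for o in oracle[:5]]
        assert [r.reaction_ids for r in routes] == [o.reaction_ids for o in oracle[:5]]

    def test_carnitine_oracle_route_lengths(self, carnitine_db):
        cfg = gi_human_config(carnitine_db, ["L-CARNITINE"], ["TMAO"], k=3, max_len=7)
        oracle = enumerate_routes_oracle(carnitine_db, cfg)
        assert [len(r.steps) for r in oracle[:3]] == [2, 6, 6]

    def test_single_arc_network_has_one_route(self):
        db = orr.gen_planted_network(0, route_len=1, n_decoys=0).db
        cfg = full_config(db, ["P-000"], ["P-001"], k=5, max_len=3)
        assert len(enumerate_routes_oracle(db, cfg)) == 1

    def test_route_count_matches_independent_graph_enumeration(self):
        networkx = pytest.importorskip("networkx")
        db = orr.gen_random_network(13, n_compounds=14, n_reactions=20, n_orgs=8)
        cids = sorted(db.compounds)
        cfg = full_config(db, [cids[0]], [cids[-1]], k=3, max_len=5)
        oracle = enumerate_routes_oracle(db, cfg)

        allowed = orr.union_reactions_for_orgs(db.org_matrix, cfg.selected_orgs)
        graph = networkx.MultiDiGraph()
        graph.add_nodes_from(db.compounds)
        for arc in db.arcs:
            if arc.reaction_id in allowed:
                graph.add_edge(arc.from_compound, arc.to_compound, reaction=arc.reaction_id)
        count = 0
        for path in networkx.all_simple_edge_paths(
            graph, cids[0], cids[-1], cutoff=cfg.max_len
        ):
            rids = [graph.edges[e]["reaction"] for e in path]
            if len(set(rids)) == len(rids):  # no reaction reuse
                count += 1
        assert len(oracle) == count


class TestMonotonicityAndDeterminism:
    @pytest.mark.parametrize("weight", ["w_reaction", "w_atom_lost", "w_switch"])
    def test_raising_one_weight_never_lowers_best_cost(self, weight):
        for seed in range(8):
            db = orr.gen_random_network(seed, n_compounds=10, n_reactions=14, n_orgs=6)
            cids = sorted(db.compounds)
            base = full_config(db, [cids[0]], [cids[-1]], k=1, max_len=5)
            bumped = SearchConfig(
                **{
                    **{f.name: getattr(base, f.name) for f in base.__dataclass_fields__.values()},
                    weight: getattr(base, weight) * 2 + 1,
                }
            )
            lo, _ = search_routes(db, base)
            hi, _ = search_routes(db, bumped)
            if lo and hi:
                assert hi[0].cost.total >= lo[0].cost.total

    def test_accumulated_cost_non_decreasing_along_returned_routes(self, trp_db):
        cfg = gi_human_config(trp_db, ["L-TRYPTOPHAN"], ["INDOXYL-SULFATE"], k=3, max_len=9)
        routes, _ = search_routes(trp_db, cfg)
        for route in routes:
            prev = 0.0
            for n in range(len(route.steps) + 1):
                prefix = orr.search._build_route(trp_db, cfg, route.start_compound, route.steps[:n])
                assert prefix.cost.total >= prev
                prev = prefix.cost.total

    def test_identical_runs_identical_output(self, trp_db):
        cfg = gi_human_config(trp_db, ["L-TRYPTOPHAN"], ["INDOXYL-SULFATE"], k=3, max_len=9)
        a, _ = search_routes(trp_db, cfg)
        b, _ = search_routes(trp_db, cfg)
        assert [r.reaction_ids for r in a] == [r.reaction_ids for r in b]

    def test_results_sorted_by_cost_then_steps_then_lexicographic(self, trp_routes):
        keys = [(r.cost.total, len(r.steps), r.reaction_ids) for r in trp_routes]
        assert keys == sorted(keys)
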