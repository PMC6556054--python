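"""Packaged example networks and seed-controlled network generators.

Three hand-built networks reconstruct well-studied gut-microbiome
transformations at desk scale, so every capability of the package can be
exercised without any external database:

* **tryptophan** — L-tryptophan -> indole (microbial) -> indoxyl -> indoxyl
  sulfate (host liver), with a lossier alternative first step and a longer
  decoy path; the 9-atom indole moiety is conserved over 3 steps and one
  organism switch separates microbes from host.
* **carnitine** — L-carnitine -> trimethylamine (microbial) -> trimethylamine
  N-oxide (host), plus two 6-step CoA-ester detours through
  gamma-butyrobetaine that differ only in their first reaction; the 4-atom
  trimethylammonium moiety is conserved throughout.
* **ahl** (autoinducers) — S-adenosyl-L-methionine -> four acyl-homoserine
  lactones -> L-homoserine lactone; one organism carries both synthase and
  lactonase activities so no switch is needed, while a second organism
  possesses only the lactonase.  SAM also feeds twenty irrelevant high
  fan-out methyl-transfer reactions.

Organism counts are small stand-ins for database-scale counts: route
structure, conserved atoms and switches are the invariants, not community
sizes.  ``gen_random_network`` and ``gen_planted_network`` produce
reproducible random and planted-optimum instances for property tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .model import AtomMap, Compound, Reaction, RouteDB, build_db
from .orgsets import Organism, OrganismMatrix, OrgBitset
from .search import (
    DEFAULT_W_ATOM_LOST,
    DEFAULT_W_REACTION,
    DEFAULT_W_SWITCH,
    SearchConfig,
    enumerate_routes_oracle,
)

__all__ = [
    "GI_HUMAN_QUERY",
    "PlantedNetwork",
    "build_trp_fixture",
    "build_carnitine_fixture",
    "build_ahl_fixture",
    "gen_random_network",
    "gen_planted_network",
]

#: Query selecting the gut community plus the human host in the packaged
#: fixtures (all gastrointestinal-tract organisms, union Homo sapiens).
GI_HUMAN_QUERY = ("gastrointestinal-tract", "Homo sapiens")

_GI = "gastrointestinal-tract"


def _ident(n: int) -> tuple[tuple[int, int], ...]:
    return tuple((i, i) for i in range(n))


def _pairs(*pairs: tuple[int, int]) -> tuple[tuple[int, int], ...]:
    return tuple(pairs)


# ---------------------------------------------------------------------------
# tryptophan -> indoxyl sulfate


def build_trp_fixture() -> RouteDB:
    """Gut tryptophan degradation to the uremic toxin indoxyl sulfate.

    Heavy-atom layouts: L-tryptophan C11H12N2O2 has 15 heavy atoms, indices
    0-7 ring carbons, 8 ring nitrogen (the 9-atom indole moiety), 9-11 side
    chain carbons, 12 amino nitrogen, 13-14 carboxyl oxygens.
    """
    indole9 = ("C",) * 8 + ("N",)
    compounds = [
        Compound("L-TRYPTOPHAN", "L-tryptophan", indole9 + ("C", "C", "C", "N", "O", "O")),
        Compound("INDOLE", "indole", indole9),
        Compound("INDOXYL", "indoxyl", indole9 + ("O",)),
        Compound(
            "INDOXYL-SULFATE", "indoxyl sulfate", indole9 + ("O", "S", "O", "O", "O")
        ),
        Compound("WATER", "water", ("O",)),
        Compound("PYRUVATE", "pyruvate", ("C", "C", "C", "O", "O", "O")),
        Compound("AMMONIA", "ammonia", ("N",)),
        Compound("OXYGEN-MOLECULE", "dioxygen", ("O", "O")),
        Compound("PAPS", "3'-phosphoadenylyl sulfate (stub)", ("S", "O", "O", "O", "P")),
        Compound("PAP", "adenosine 3',5'-bisphosphate (stub)", ("P", "O", "O")),
        Compound("SIDE-KETO", "2-oxo side product", ("C", "C", "C", "C", "O", "O", "O")),
        Compound("FRAG-1", "ring-cleavage fragment", ("C", "C", "C", "N", "O", "O")),
        Compound("DECOY-A1", "oxidized intermediate a1", ("C",) * 8 + ("N", "O", "O", "O")),
        Compound("DECOY-A2", "oxidized intermediate a2", ("C",) * 8 + ("N", "O")),
        Compound("DECOY-A3", "oxidized intermediate a3", ("C",) * 7 + ("N", "O")),
        Compound(
            "INDOLE-3-PYRUVATE",
            "indole-3-pyruvate",
            indole9 + ("C", "C", "C", "O", "O", "O"),
        ),
    ]
    reactions = [
        Reaction("RXN-TNASE-A", ("L-TRYPTOPHAN", "WATER"), ("INDOLE", "PYRUVATE", "AMMONIA")),
        Reaction("RXN-TNASE-B", ("L-TRYPTOPHAN", "WATER"), ("INDOLE", "SIDE-KETO")),
        Reaction("RXN-IND-MONOOX", ("INDOLE", "OXYGEN-MOLECULE"), ("INDOXYL",)),
        Reaction("RXN-IND-SULFO", ("INDOXYL", "PAPS"), ("INDOXYL-SULFATE", "PAP")),
        Reaction("RXN-TRP-CLEAVE-LOSSY", ("L-TRYPTOPHAN",), ("INDOLE", "FRAG-1")),
        Reaction("RXN-DECOY-A1", ("L-TRYPTOPHAN",), ("DECOY-A1",)),
        Reaction("RXN-DECOY-A2", ("DECOY-A1",), ("DECOY-A2",)),
        Reaction("RXN-DECOY-A3", ("DECOY-A2",), ("DECOY-A3",)),
        Reaction("RXN-DECOY-A4", ("DECOY-A3", "PAPS"), ("INDOXYL-SULFATE",)),
        Reaction("RXN-TRP-AMINOTRANSFERASE", ("L-TRYPTOPHAN",), ("INDOLE-3-PYRUVATE",)),
    ]
    id9 = _ident(9)
    atom_maps = [
        AtomMap("RXN-TNASE-A", "L-TRYPTOPHAN", "INDOLE", id9),
        AtomMap("RXN-TNASE-B", "L-TRYPTOPHAN", "INDOLE", id9),
        AtomMap("RXN-IND-MONOOX", "INDOLE", "INDOXYL", id9),
        AtomMap("RXN-IND-SULFO", "INDOXYL", "INDOXYL-SULFATE", _ident(10)),
        AtomMap("RXN-TRP-CLEAVE-LOSSY", "L-TRYPTOPHAN", "INDOLE", _ident(6)),
        AtomMap("RXN-DECOY-A1", "L-TRYPTOPHAN", "DECOY-A1", id9),
        AtomMap("RXN-DECOY-A2", "DECOY-A1", "DECOY-A2", _ident(8)),
        AtomMap("RXN-DECOY-A3", "DECOY-A2", "DECOY-A3", _ident(7)),
        AtomMap("RXN-DECOY-A4", "DECOY-A3", "INDOXYL-SULFATE", _ident(7)),
        AtomMap("RXN-TRP-AMINOTRANSFERASE", "L-TRYPTOPHAN", "INDOLE-3-PYRUVATE", id9),
    ]
    organisms = [
        Organism("GUT-1", "Escherichia coli (gut isolate)", (_GI,)),
        Organism("GUT-2", "Bacteroides fragilis", (_GI,)),
        Organism("GUT-3", "Clostridium sporogenes", (_GI,)),
        Organism("GUT-4", "Lactobacillus reuteri", (_GI,)),
        Organism("GUT-5", "Bifidobacterium longum", (_GI,)),
        Organism("HUMAN", "Homo sapiens", ("host",)),
        Organism("SKIN-1", "Staphylococcus epidermidis", ("skin",)),
    ]
    membership = {
        "RXN-TNASE-A": ["GUT-1", "GUT-2", "GUT-3"],
        "RXN-TNASE-B": ["GUT-1", "GUT-2", "GUT-3", "GUT-4", "GUT-5"],
        "RXN-IND-MONOOX": ["HUMAN"],
        "RXN-IND-SULFO": ["HUMAN"],
        "RXN-TRP-CLEAVE-LOSSY": ["GUT-4", "GUT-5", "SKIN-1"],
        "RXN-DECOY-A1": ["GUT-2", "GUT-3"],
        "RXN-DECOY-A2": ["GUT-2", "GUT-3"],
        "RXN-DECOY-A3": ["GUT-2", "GUT-3"],
        "RXN-DECOY-A4": ["HUMAN"],
        "RXN-TRP-AMINOTRANSFERASE": ["GUT-1", "SKIN-1"],
    }
    matrix = OrganismMatrix.from_membership(organisms, membership)
    return build_db(compounds, reactions, atom_maps, matrix)


# ---------------------------------------------------------------------------
# carnitine -> TMAO


def build_carnitine_fixture() -> RouteDB:
    """Gut carnitine degradation to trimethylamine N-oxide.

    L-carnitine C7H15NO3 has 11 heavy atoms: index 0 the quaternary nitrogen,
    1-3 the methyl carbons (the 4-atom trimethylammonium moiety), 4-7 chain
    carbons, 8 the hydroxyl oxygen, 9-10 carboxyl oxygens.  CoA thioesters
    are modeled as the betaine skeleton plus a 3-atom (S, C, C) stub.
    """
    tma4 = ("N", "C", "C", "C")
    carnitine = tma4 + ("C", "C", "C", "C", "O", "O", "O")
    coa_ester = ("N",) + ("C",) * 7 + ("O", "O") + ("S", "C", "C")  # no hydroxyl O
    compounds = [
        Compound("L-CARNITINE", "L-carnitine", carnitine),
        Compound("TMA", "trimethylamine", tma4),
        Compound("TMAO", "trimethylamine N-oxide", tma4 + ("O",)),
        Compound("CARNITINYL-COA", "L-carnitinyl-CoA (stub)", carnitine + ("S", "C", "C")),
        Compound("CROTONOBETAINYL-COA", "crotonobetainyl-CoA (stub)", coa_ester),
        Compound("GBB-COA", "gamma-butyrobetainyl-CoA (stub)", coa_ester),
        Compound(
            "GAMMA-BUTYROBETAINE", "gamma-butyrobetaine", ("N",) + ("C",) * 7 + ("O", "O")
        ),
        Compound("COA", "coenzyme A (stub)", ("S", "C", "C")),
        Compound("WATER", "water", ("O",)),
        Compound("OXYGEN-MOLECULE", "dioxygen", ("O", "O")),
        Compound(
            "MALATE-SEMIALDEHYDE", "malate semialdehyde", ("C", "C", "C", "C", "O", "O", "O")
        ),
        Compound(
            "SUCCINATE-SEMIALDEHYDE",
            "succinate semialdehyde",
            ("C", "C", "C", "C", "O", "O", "O"),
        ),
    ]
    reactions = [
        Reaction(
            "RXN-CARNITINE-OXYGENASE",
            ("L-CARNITINE", "OXYGEN-MOLECULE"),
            ("TMA", "MALATE-SEMIALDEHYDE"),
        ),
        Reaction("RXN-TMA-MONOOXYGENASE", ("TMA", "OXYGEN-MOLECULE"), ("TMAO", "WATER")),
        Reaction("RXN-CRNCOA-LIGASE", ("L-CARNITINE", "COA"), ("CARNITINYL-COA",)),
        Reaction(
            "RXN-CRNCOA-TRANSFERASE",
            ("L-CARNITINE", "GBB-COA"),
            ("CARNITINYL-COA", "GAMMA-BUTYROBETAINE"),
        ),
        Reaction("RXN-CTBCOA-DEHYDRATASE", ("CARNITINYL-COA",), ("CROTONOBETAINYL-COA", "WATER")),
        Reaction("RXN-GBBCOA-REDUCTASE", ("CROTONOBETAINYL-COA",), ("GBB-COA",)),
        Reaction("RXN-GBBCOA-HYDROLASE", ("GBB-COA", "WATER"), ("GAMMA-BUTYROBETAINE", "COA")),
        Reaction(
            "RXN-GBB-OXYGENASE",
            ("GAMMA-BUTYROBETAINE", "OXYGEN-MOLECULE"),
            ("TMA", "SUCCINATE-SEMIALDEHYDE"),
        ),
    ]
    id4 = _ident(4)
    dehydratase_map = tuple((i, i) for i in range(8)) + _pairs(
        (9, 8), (10, 9), (11, 10), (12, 11), (13, 12)
    )
    atom_maps = [
        AtomMap("RXN-CARNITINE-OXYGENASE", "L-CARNITINE", "TMA", id4),
        AtomMap("RXN-TMA-MONOOXYGENASE", "TMA", "TMAO", id4),
        AtomMap("RXN-CRNCOA-LIGASE", "L-CARNITINE", "CARNITINYL-COA", _ident(11)),
        AtomMap("RXN-CRNCOA-TRANSFERASE", "L-CARNITINE", "CARNITINYL-COA", _ident(11)),
        AtomMap("RXN-CTBCOA-DEHYDRATASE", "CARNITINYL-COA", "CROTONOBETAINYL-COA", dehydratase_map),
        AtomMap("RXN-GBBCOA-REDUCTASE", "CROTONOBETAINYL-COA", "GBB-COA", _ident(13)),
        AtomMap("RXN-GBBCOA-HYDROLASE", "GBB-COA", "GAMMA-BUTYROBETAINE", _ident(10)),
        AtomMap("RXN-GBB-OXYGENASE", "GAMMA-BUTYROBETAINE", "TMA", id4),
    ]
    organisms = [
        Organism("GUT-1", "Acinetobacter baumannii (gut isolate)", (_GI,)),
        Organism("GUT-2", "Escherichia coli (gut isolate)", (_GI,)),
        Organism("GUT-3", "Citrobacter freundii", (_GI,)),
        Organism("GUT-4", "Emergencia timonensis", (_GI,)),
        Organism("HUMAN", "Homo sapiens", ("host",)),
    ]
    coa_path = ["GUT-1", "GUT-2", "GUT-3", "GUT-4"]
    membership = {
        "RXN-CARNITINE-OXYGENASE": ["GUT-1", "GUT-2", "GUT-3"],
        "RXN-TMA-MONOOXYGENASE": ["HUMAN"],
        "RXN-CRNCOA-LIGASE": coa_path,
        "RXN-CRNCOA-TRANSFERASE": coa_path,
        "RXN-CTBCOA-DEHYDRATASE": coa_path,
        "RXN-GBBCOA-REDUCTASE": coa_path,
        "RXN-GBBCOA-HYDROLASE": coa_path,
        "RXN-GBB-OXYGENASE": coa_path,
    }
    matrix = OrganismMatrix.from_membership(organisms, membership)
    return build_db(compounds, reactions, atom_maps, matrix)


# ---------------------------------------------------------------------------
# SAM -> AHLs -> homoserine lactone


def build_ahl_fixture() -> RouteDB:
    """Synthesis and degradation of acyl-homoserine lactone autoinducers.

    S-adenosyl-L-methionine (27 heavy atoms) donates its homoserine part;
    indices 0-6 are the homoserine-lactone moiety (C,C,C,C,N,O,O) shared with
    every AHL and with L-homoserine lactone, index 7 the sulfonium sulfur,
    8-18 adenosyl/methyl carbons, 19-23 adenine nitrogens, 24-26 oxygens.
    """
    moiety = ("C", "C", "C", "C", "N", "O", "O")
    sam = moiety + ("S",) + ("C",) * 11 + ("N",) * 5 + ("O",) * 3
    chains = {"C04": 4, "C06": 6, "C08": 8, "C12": 12}
    compounds = [
        Compound("S-ADENOSYLMETHIONINE", "S-adenosyl-L-methionine", sam),
        Compound("L-HOMOSERINE-LACTONE", "L-homoserine lactone", moiety),
        Compound("MTA", "5'-methylthioadenosine (stub)", ("S",) + ("C",) * 10 + ("N",) * 5 + ("O", "O")),
        Compound("ACP", "acyl carrier protein (stub)", ("S", "C", "C")),
        Compound("WATER", "water", ("O",)),
    ]
    for tag, n in chains.items():
        compounds.append(
            Compound(f"AHL-{tag}", f"N-acyl ({tag}) homoserine lactone", moiety + ("C",) * n + ("O",))
        )
        compounds.append(
            Compound(f"ACYL-ACP-{tag}", f"{tag} acyl-ACP (stub)", ("C",) * n + ("O", "S"))
        )
        compounds.append(
            Compound(f"FATTY-ACID-{tag}", f"{tag} fatty acid", ("C",) * n + ("O", "O"))
        )
    # twenty irrelevant methyl-transfer sinks exercising SAM's high fan-out
    n_decoys = 20
    for i in range(1, n_decoys + 1):
        compounds.append(
            Compound(
                f"METHYL-SINK-{i:02d}",
                f"methylated product {i:02d}",
                ("C",) * 10 + ("N",) * 3 + ("O",) * 2,
            )
        )

    reactions = []
    atom_maps = []
    id7 = _ident(7)
    for tag in chains:
        reactions.append(
            Reaction(
                f"RXN-AHL-SYNTHASE-{tag}",
                ("S-ADENOSYLMETHIONINE", f"ACYL-ACP-{tag}"),
                (f"AHL-{tag}", "MTA", "ACP"),
            )
        )
        atom_maps.append(
            AtomMap(f"RXN-AHL-SYNTHASE-{tag}", "S-ADENOSYLMETHIONINE", f"AHL-{tag}", id7)
        )
        reactions.append(
            Reaction(
                f"RXN-AHL-LACTONASE-{tag}",
                (f"AHL-{tag}", "WATER"),
                ("L-HOMOSERINE-LACTONE", f"FATTY-ACID-{tag}"),
            )
        )
        atom_maps.append(
            AtomMap(f"RXN-AHL-LACTONASE-{tag}", f"AHL-{tag}", "L-HOMOSERINE-LACTONE", id7)
        )
    decoy_map = (
        tuple((8 + i, i) for i in range(10))
        + tuple((19 + i, 10 + i) for i in range(3))
        + tuple((24 + i, 13 + i) for i in range(2))
    )
    for i in range(1, n_decoys + 1):
        rid = f"RXN-SAM-METHYLTRANSFER-{i:02d}"
        reactions.append(
            Reaction(rid, ("S-ADENOSYLMETHIONINE",), (f"METHYL-SINK-{i:02d}",))
        )
        atom_maps.append(
            AtomMap(rid, "S-ADENOSYLMETHIONINE", f"METHYL-SINK-{i:02d}", decoy_map)
        )

    organisms = [
        Organism("PSEUDO", "Pseudomonas aeruginosa 2_1_26", (_GI,)),
        Organism("GUT-1", "Yersinia enterocolitica", (_GI,)),
        Organism("GUT-2", "Serratia marcescens", (_GI,)),
        Organism("GUT-3", "Enterobacter cloacae", (_GI,)),
        Organism("GUT-4", "Aeromonas hydrophila", (_GI,)),
        Organism("GUT-5", "Hafnia alvei", (_GI,)),
        Organism("RALSTO", "Ralstonia pickettii 5_7_47FAA", (_GI,)),
        Organism("HUMAN", "Homo sapiens", ("host",)),
    ]
    synth_orgs = ["PSEUDO", "GUT-1", "GUT-2", "GUT-3", "GUT-4", "GUT-5"]
    decoy_orgs = ["GUT-1", "GUT-2", "GUT-3", "GUT-4", "GUT-5", "HUMAN"]
    membership = {}
    for tag in chains:
        membership[f"RXN-AHL-SYNTHASE-{tag}"] = synth_orgs
        membership[f"RXN-AHL-LACTONASE-{tag}"] = ["PSEUDO", "RALSTO"]
    for i in range(1, n_decoys + 1):
        membership[f"RXN-SAM-METHYLTRANSFER-{i:02d}"] = [
            decoy_orgs[i % len(decoy_orgs)],
            decoy_orgs[(i + 2) % len(decoy_orgs)],
        ]
    matrix = OrganismMatrix.from_membership(organisms, membership)
    return build_db(compounds, reactions, atom_maps, matrix)


# ---------------------------------------------------------------------------
# random networks


def gen_random_network(
    seed: int,
    n_compounds: int = 12,
    n_reactions: int = 18,
    n_orgs: int = 8,
    n_tags: int = 3,
    mean_atoms: int = 6,
    map_density: float = 0.6,
) -> RouteDB:
    """Reproducible random network.

    Every compound starts with a carbon so any (substrate, product) pair
    admits at least one same-element atom pair; every reaction gets a mapped
    arc for its first substrate/product pair, further pairs are mapped with
    probability ``map_density``; every reaction occurs in at least one
    organism, with per-reaction prevalence drawn uniformly.
    """
    if n_compounds < 2 or n_reactions < 1 or n_orgs < 1 or n_tags < 1:
        raise ValueError("network dimensions must be positive (and >= 2 compounds)")
    if not 0 < map_density <= 1:
        raise ValueError("map_density must be in (0, 1]")
    rng = random.Random(seed)
    elements = ["C", "C", "C", "N", "O"]

    compounds = []
    for i in range(n_compounds):
        size = max(1, int(round(rng.gauss(mean_atoms, mean_atoms / 3))))
        atoms = ("C",) + tuple(rng.choice(elements) for _ in range(size - 1))
        compounds.append(Compound(f"CPD-{i:03d}", f"compound {i}", atoms))
    by_id = {c.id: c for c in compounds}

    reactions = []
    atom_maps = []
    for r in range(n_reactions):
        n_sub = rng.randint(1, min(2, n_compounds - 1))
        n_prod = rng.randint(1, min(2, n_compounds - n_sub))
        chosen = rng.sample([c.id for c in compounds], n_sub + n_prod)
        subs, prods = tuple(chosen[:n_sub]), tuple(chosen[n_sub:])
        rid = f"RXN-{r:03d}"
        reactions.append(Reaction(rid, subs, prods, reversible=rng.random() < 0.2))
        for si, s in enumerate(subs):
            for pi, p in enumerate(prods):
                first = si == 0 and pi == 0
                if not first and rng.random() >= map_density:
                    continue
                pairs = _random_atom_pairs(rng, by_id[s].atoms, by_id[p].atoms)
                atom_maps.append(AtomMap(rid, s, p, pairs))

    organisms = [
        Organism(
            f"ORG-{j:03d}",
            f"organism {j}",
            tuple(sorted(rng.sample([f"TAG-{t}" for t in range(n_tags)], rng.randint(1, n_tags)))),
        )
        for j in range(n_orgs)
    ]
    membership = {}
    for r in range(n_reactions):
        prevalence = rng.uniform(0.15, 0.9)
        members = [o.id for o in organisms if rng.random() < prevalence]
        if not members:
            members = [rng.choice(organisms).id]
        membership[f"RXN-{r:03d}"] = members

    matrix = OrganismMatrix.from_membership(organisms, membership)
    return build_db(compounds, reactions, atom_maps, matrix)


def _random_atom_pairs(
    rng: random.Random, sub_atoms: tuple[str, ...], prod_atoms: tuple[str, ...]
) -> tuple[tuple[int, int], ...]:
    """Random non-empty injective same-element pairing of two atom lists."""
    candidates: list[tuple[int, int]] = []
    for element in sorted(set(sub_atoms) & set(prod_atoms)):
        si = [i for i, a in enumerate(sub_atoms) if a == element]
        pi = [j for j, a in enumerate(prod_atoms) if a == element]
        rng.shuffle(si)
        rng.shuffle(pi)
        candidates.extend(zip(si, pi))
    k = rng.randint(1, len(candidates))
    return tuple(sorted(rng.sample(candidates, k)))


# ---------------------------------------------------------------------------
# planted networks


@dataclass(frozen=True)
class PlantedNetwork:
    """A network with a known uniquely-optimal route.

    ``config`` is the search configuration under which ``planted_route`` is
    the strict optimum (verified at generation time by the enumeration
    oracle); ``planted_cost`` its total cost under the default weights.
    """

    db: RouteDB
    planted_route: tuple[str, ...]
    planted_cost: float
    config: SearchConfig


def gen_planted_network(
    seed: int,
    route_len: int = 4,
    n_decoys: int = 4,
    max_attempts: int = 25,
) -> PlantedNetwork:
    """Plant a full-atom-transfer, single-organism route and surround it with
    strictly costlier decoys (detours, switch-forcing shortcuts, dead ends).

    The optimality guarantee is checked with the enumeration oracle at
    generation time; generation retries with a derived sub-seed and raises if
    it cannot satisfy the guarantee.
    """
    if route_len < 1:
        raise ValueError("route_len must be >= 1")
    last_error = None
    for attempt in range(max_attempts):
        rng = random.Random((seed * 1_000_003 + attempt) % (2**31))
        net = _plant_once(rng, route_len, n_decoys)
        routes = enumerate_routes_oracle(net.db, net.config)
        if (
            routes
            and routes[0].reaction_ids == net.planted_route
            and routes[0].cost.total == net.planted_cost
            and (len(routes) == 1 or routes[1].cost.total > net.planted_cost)
        ):
            return net
        last_error = f"attempt {attempt}: planted route not uniquely optimal"
    raise RuntimeError(f"planted-network generation failed: {last_error}")


def _plant_once(rng: random.Random, route_len: int, n_decoys: int) -> PlantedNetwork:
    atoms = ("C",) * 6
    compounds = [
        Compound(f"P-{i:03d}", f"planted compound {i}", atoms) for i in range(route_len + 1)
    ]
    reactions = []
    atom_maps = []
    planted = []
    for i in range(route_len):
        rid = f"RXN-PLANT-{i:02d}"
        planted.append(rid)
        reactions.append(Reaction(rid, (f"P-{i:03d}",), (f"P-{i + 1:03d}",)))
        atom_maps.append(AtomMap(rid, f"P-{i:03d}", f"P-{i + 1:03d}", _ident(6)))
    membership = {rid: ["ORG-MAIN"] for rid in planted}

    for d in range(n_decoys):
        kind = d % 3
        if kind == 0:  # two-step detour around one planted edge (+1 step)
            j = rng.randrange(route_len)
            det = f"D-{d:03d}"
            compounds.append(Compound(det, f"detour compound {d}", atoms))
            for rid, src, dst in (
                (f"RXN-DECOY-{d:02d}-A", f"P-{j:03d}", det),
                (f"RXN-DECOY-{d:02d}-B", det, f"P-{j + 1:03d}"),
            ):
                reactions.append(Reaction(rid, (src,), (dst,)))
                atom_maps.append(AtomMap(rid, src, dst, _ident(6)))
                membership[rid] = ["ORG-MAIN"]
        elif kind == 1 and route_len >= 2:
            # lossy shortcut owned by the other organism; never spans the whole
            # route from its start, so taking it always costs >= 1 switch
            j = rng.randrange(route_len)
            span = min(3, route_len - j)
            if j == 0 and span == route_len:
                j, span = 1, min(3, route_len - 1)
            rid = f"RXN-DECOY-{d:02d}-S"
            src, dst = f"P-{j:03d}", f"P-{j + span:03d}"
            reactions.append(Reaction(rid, (src,), (dst,)))
            atom_maps.append(AtomMap(rid, src, dst, _pairs((0, 0), (1, 1))))
            membership[rid] = ["ORG-ALT"]
        else:  # dead-end branch
            j = rng.randrange(route_len + 1)
            sink = f"X-{d:03d}"
            compounds.append(Compound(sink, f"dead end {d}", atoms))
            rid = f"RXN-DECOY-{d:02d}-X"
            reactions.append(Reaction(rid, (f"P-{j:03d}",), (sink,)))
            atom_maps.append(AtomMap(rid, f"P-{j:03d}", sink, _ident(6)))
            membership[rid] = [rng.choice(["ORG-MAIN", "ORG-ALT"])]

    organisms = [
        Organism("ORG-MAIN", "primary degrader", ("planted",)),
        Organism("ORG-ALT", "decoy specialist", ("decoy",)),
    ]
    matrix = OrganismMatrix.from_membership(organisms, membership)
    db = build_db(compounds, reactions, atom_maps, matrix)
    config = SearchConfig(
        start_set=("P-000",),
        goal_set=(f"P-{route_len:03d}",),
        selected_orgs=OrgBitset.full(matrix.universe_size),
        k=2,
        max_len=route_len + 1,
    )
    planted_cost = DEFAULT_W_REACTION * route_len  # full transfer, no switch
    return PlantedNetwork(db, tuple(planted), planted_cost, config)
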