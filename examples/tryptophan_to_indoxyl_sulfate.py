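"""Route search: gut-microbial tryptophan degradation to indoxyl sulfate.

Builds the packaged tryptophan network, selects all gastrointestinal-tract
organisms plus the human host, and asks for the 3 cheapest routes from
L-tryptophan to the uremic toxin indoxyl sulfate.
"""

from orgroutes import (
    GI_HUMAN_QUERY,
    SearchConfig,
    build_trp_fixture,
    search_routes,
    select_organisms,
)

db = build_trp_fixture()
selected = select_organisms(db.org_matrix, GI_HUMAN_QUERY)
config = SearchConfig(
    start_set=("L-TRYPTOPHAN",),
    goal_set=("INDOXYL-SULFATE",),
    selected_orgs=selected,
    k=3,
    max_len=9,
)
routes, status = search_routes(db, config)

print(f"status: {status}")
for rank, route in enumerate(routes, start=1):
    print(
        f"route {rank}: {len(route.steps)} steps, "
        f"{route.conserved_atoms} conserved atoms, {route.switches} switch(es), "
        f"cost {route.cost.total:g}"
    )
    print("  " + " -> ".join(route.compound_chain))

# The best route keeps the 9-atom indole moiety of tryptophan's 15 heavy
# atoms across 3 reactions, with one hand-off from gut microbes (which make
# indole) to the human host (which oxidizes and sulfates it).
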