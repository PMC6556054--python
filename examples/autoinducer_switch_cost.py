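"""Organism-switch cost contrast on the autoinducer network.

Four acyl-homoserine lactones (AHLs) connect S-adenosyl-L-methionine to
L-homoserine lactone in 2 steps each.  One organism carries both synthase
and lactonase, so the minimum-switch strategy needs zero switches and its
step-2 organism set shrinks to that single organism.  Disabling switch
minimization (switch cost 0) annotates each step independently, revealing a
second organism that only degrades the signal.
"""

from orgroutes import (
    GI_HUMAN_QUERY,
    SearchConfig,
    build_ahl_fixture,
    search_routes,
    select_organisms,
)

db = build_ahl_fixture()
matrix = db.org_matrix
selected = select_organisms(matrix, GI_HUMAN_QUERY)

for w_switch in (30.0, 0.0):
    config = SearchConfig(
        start_set=("S-ADENOSYLMETHIONINE",),
        goal_set=("L-HOMOSERINE-LACTONE",),
        selected_orgs=selected,
        w_switch=w_switch,
        k=4,
        max_len=4,
    )
    routes, _ = search_routes(db, config)
    route = routes[0]
    names = [
        sorted(matrix.organism_at(i).name for i in seg.organisms.indices())
        for seg in route.segments
    ]
    print(f"switch cost {w_switch:g}: {route.switches} switch(es); segments:")
    for seg_names in names:
        print("   ", seg_names)

# With cost 30 the lactonase step's segment is the single spanning organism;
# with cost 0 the per-step sets also show the degrade-only organism, an
# asymmetry relevant to quorum-sensing interference.
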