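# Methods

## Problem and model

Given a network of reactions shared across a set of organisms, `orgroutes`
searches for *routes*: linear successions of reactions converting a start
metabolite into a goal metabolite through intermediates. Three properties
are minimized jointly as a weighted sum:

* **route length** — number of reactions;
* **atom loss** — heavy atoms of the start compound no longer present at the
  route frontier, obtained by composing per-step atom mappings;
* **organism switches** — hand-offs between community members, detected by a
  running intersection of organism sets.

The model is deliberately compartment-agnostic: every reaction of every
selected organism is treated as accessible, and no transport step is
required at a switch boundary. This trades false positives for recall and
is the standard simplification for exploratory community-level analysis.
Stoichiometry, thermodynamics, and flux constraints are out of scope; a
route is a qualitative, atom-traceable chain, not a flux solution.

### Atom bookkeeping

Compounds carry ordered heavy-atom element lists; hydrogens are excluded
(their fate is not informative for route plausibility and standard atom maps
omit them). An atom map is a partial injective pairing between the atoms of
one substrate and one product; validation rejects index reuse, out-of-range
indices, and cross-element pairs. Each mapped (substrate, product) pair of
a reaction yields one *traversal arc*; reversible reactions (an explicit
input flag, never inferred) also yield the inverse arc. Unmapped
co-substrates and co-products take no part in traversal, matching the
"side products not shown" semantics of linear route displays.

Tracking composes the chain of partial maps: `alive` maps frontier-compound
atom indices to their origin indices in the start compound. Composition is
associative and the alive set shrinks monotonically, which makes the atom
component of the accumulated path cost non-decreasing — a property the
search relies on. Atoms introduced mid-route carry no origin and never count
as conserved.

### Switch minimization

The detector keeps a set S of selected organisms able to catalyze every
reaction since the last switch. S starts as the selected organisms
containing the first reaction and is intersected with each new reaction's
organism set; when the intersection would be empty, one switch is counted
and S restarts from the new reaction's (selection-restricted) organism set.
On reset, S is intersected with the user's selection — the reset set is the
selected organisms containing the new reaction, not all organisms containing
it. Greedy running intersection attains the minimum achievable number of
contiguous segments (extending the current segment never forecloses a later
segmentation — the standard greedy interval argument), and each emitted
segment set is maximal for its segment. Rather than assuming this, the test
suite checks greedy counts against an exhaustive contiguous-partition oracle
(`min_segments_oracle`, 2^(n−1) partitions, n ≤ 16) on hundreds of random
instances, and checks maximality organism-by-organism.

Organism sets are fixed-width dense bit vectors over a universe frozen at
matrix construction (arbitrary-precision integers; intersection, union,
popcount are single operations). A sparse representation is deliberately
absent: presence rows are dense in practice because common reactions occur
in many organisms. Operations across mismatched universes raise immediately.

### Search

`search_routes` is uniform-cost best-first over partial simple routes
(states: current compound, alive map, running set S, arcs taken). Because
each cost component is non-negative and non-decreasing under extension, the
priority queue pops partial routes in ascending accumulated cost, and the
first k goal pops are exactly the k cheapest routes — verified against
`enumerate_routes_oracle`, an independent exhaustive DFS ranking, on 50+
random networks per test run. No heuristic is used (future atom loss has no
admissible estimate without lookahead) and no dominance pruning is applied;
at the network sizes this package targets, plain best-first enumeration is
already fast, and stopping after the k-th goal pop bounds the work sharply.

Details and conventions:

* **Simple routes**: no repeated compound, no repeated reaction (a reaction
  with several mapped arcs could otherwise recur between disjoint compound
  pairs). Cycles cannot lower any cost component.
* **Tie-break**: ascending (cost, step count, lexicographic reaction-id
  sequence); output is bitwise reproducible across runs.
* **k-best** counts distinct reaction sequences, not distinct costs.
* **start = goal** yields a zero-step route of cost 0.
* **Excluded intermediates** (optional) may begin or end a route but are
  never expanded through; there is no built-in currency-metabolite
  blacklist, since the atom-loss weight already penalizes low-transfer hops.
* **Timeout** is checked between expansions; on expiry the routes found so
  far are returned with status `"timeout"` instead of `"complete"`.
* **Switch cost 0** disables switch minimization: route ranking ignores
  switches (the weight is zero) and reported segments become independent
  per-reaction organism sets rather than maximal running-intersection
  segments. `Route.switches` still reports the minimal count. This is what
  makes a degrade-only organism visible in a downstream step's set, as in
  the autoinducer example.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `w_reaction` | 10 | cost per reaction step |
| `w_atom_lost` | 1 | cost per heavy atom of the start compound lost |
| `w_switch` | 30 | cost per organism switch (0 disables minimization) |
| `k` | 3 | routes requested |
| `max_len` | 6 | maximum reactions per route |
| `time_limit_s` | 60 | wall-clock budget |

The ratios are what matter: one switch ≈ three reactions, so the search
prefers a moderately longer single-organism route over a hand-off, and atom
losses below ten never outweigh saving a step. All weights are settable per
search and on the CLI.

## Example networks and generators

The packaged networks reconstruct three documented gut-community
transformations at desk scale, with the chemistry reduced to exactly the
atoms that matter:

* **tryptophan** — 15-heavy-atom tryptophan; maps transfer the 9-atom indole
  moiety; two alternative microbial first steps (3 vs 5 carriers), host-only
  oxidation and sulfation, one lossier first step and one 4-step decoy path.
* **carnitine** — 11-heavy-atom carnitine; maps transfer the 4-atom
  trimethylammonium moiety; direct microbial cleavage plus two 6-step
  CoA-ester detours (ligase vs transferase first step) through
  gamma-butyrobetaine. CoA thioesters carry a fixed 3-atom (S, C, C) stub
  rather than a realistic CoA atom list.
* **autoinducer** — 27-heavy-atom S-adenosyl-L-methionine feeding four AHL
  synthases (6 organisms each) and four lactonases (2 organisms, one of
  which also has the synthases); 20 extra methyl-transfer reactions give the
  start compound realistic fan-out. A documented 9-step tryptophan
  alternative whose intermediates are not in the available description is
  not reconstructed.

Organism counts are small stand-ins for database-scale communities; the
tests assert route structure, conserved atoms, and switches — quantities the
algorithm determines — not organism counts, except where a count is
structurally forced (host-only steps).

`gen_random_network(seed, ...)` produces fully reproducible random networks
(every compound is guaranteed a carbon so every compound pair admits a
same-element atom pair; every reaction gets at least one mapped arc and one
organism; per-reaction prevalence is uniform on [0.15, 0.9]).
`gen_planted_network` plants a full-transfer single-organism route and
surrounds it with strictly costlier decoys (longer detours, switch-forcing
lossy shortcuts, dead ends); uniqueness of the planted optimum is verified
by the enumeration oracle at generation time, with bounded retries.

What the generators do **not** emulate: realistic degree distributions,
currency-metabolite hubs beyond the one fan-out fixture, reaction
reversibility patterns, or correlated organism repertoires. Passing tests
therefore demonstrate algorithmic correctness (optimality, minimality,
monotonicity, determinism) on networks of this character — not predictive
accuracy on any real community reconstruction, which depends entirely on the
quality of the input network and atom maps.

## Numerical and degenerate-input choices

Costs are small exact-valued floats (weights times integer counts), so
equality comparisons in tests are safe. Determinism is enforced
structurally: frozen input orders, sorted arc generation, a total tie-break
order, and seeded `random.Random` instances in the generators. Degenerate
inputs are defined rather than undefined: empty routes segment to zero
segments, missing matrix rows read as all-zero, empty organism selections
raise (a vacuous search is an error, not an empty answer), and bundles
round-trip byte-identically.

## Problem sizes

The test suite and the acceptance script run the packaged networks
(8–28 reactions), 50 random networks of ≤ 14 compounds / 20 reactions /
8 organisms for oracle-equivalence checks, 200 random switch-minimality
instances (routes ≤ 8, ≤ 12 organisms), and 100 planted networks (routes of
1–6 steps). These sizes keep the exhaustive oracles exact while exercising
every code path; the search itself has no such limits.

## Known limitations

* Atom maps are consumed, not computed; there is no structure-based mapping.
* No transport or compartment modeling at switch boundaries: a reported
  hand-off assumes the shared intermediate is exchangeable.
* The per-route state space is exponential in the worst case; the time limit
  is the safety valve, and results under a timeout are best-so-far only.
* Reversibility must be declared in the input; fixtures use explicit
  directions throughout.
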