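# Methods

## Problem and model

`emsroute` supports dispatch decisions for emergency medical services (EMS).
Two questions are answered on a road network: *which station serves which part
of the city* (catchment delineation), and *which available ambulance reaches a
given incident fastest* (unit selection). Both are answered on a weighted
undirected graph G = (N, L): nodes carry WGS84 coordinates, edges are road
segments with length d_l (m), speed limit s_l (km/h) and optional traffic
attributes. Stations and incidents are anchored to graph nodes; geometric
(great-circle) distance is used only for that snapping step, never for
routing.

### Travel-time edge weights

A segment's free-flow traversal time is

    t_free = d_l / (1000 · s_l) · 3600   [s].

Observed traffic enters through the density k_l = n · 1000 / d_l (veh/km for
n vehicles on the segment) and the saturation ratio x = k_l / k_max ∈ [0, 1),
where k_max is the jam density. The congested traversal time is, in the
default `greenshields_division` mode,

    t = t_free / (1 − x),

the steady-state form implied by a linear speed–density relationship: time
diverges as the road approaches jam density. An alternative `as_printed` mode
computes t = t_free · (1 − x) instead. That multiplicative form appears in
some accounts of this weighting, but it *shortens* congested trips, which
contradicts both physical sense and the reported direction of effect
(time-based costs exceeding length-based costs under congestion). We keep it
selectable for comparison and fidelity but never as the default, and we do
not silently alter either formula.

Numerical guards: x is clamped at `saturation_clamp` (default 0.95) so the
division stays finite — near jam density real flows are stop-and-go and the
steady-state model is not meaningful there. Both modes reduce exactly to
t_free on an empty road. No separate intersection/signal delay is modelled;
the saturation term is the entire delay model.

### Defaults and their origin

| parameter            | default | meaning                                                                    |
|----------------------|---------|----------------------------------------------------------------------------|
| `default_speed_kmh`  | 40      | speed assigned to segments without a posted limit (typical urban average)  |
| `default_k_max`      | 100     | jam density (veh/km) when not supplied; ~one vehicle per 10 m of lane      |
| `saturation_clamp`   | 0.95    | cap on k/k_max keeping weights finite                                      |
| `default_saturation` | 0.70    | scenario-wide ratio applied to unobserved segments on request; 0.70 is the conventional boundary between adequate and strained capacity |

A segment with no vehicle-count observation is treated as free-flowing unless
a scenario saturation is explicitly requested (`default_saturation` /
`--use-default-saturation`); an observed count of zero always means an empty
road. Missing k_max defaults to the configured constant because per-segment
jam densities are rarely available in practice.

## Network Voronoi diagram (catchments)

The catchment of station p is the set of nodes whose cheapest path cost (in
meters or congested seconds) to p is no greater than to any other station.
Assignment runs one multi-source Dijkstra sweep with every station anchor
seeded at cost 0; the heap is ordered by (cost, facility_id, node), so an
exact cost tie is claimed by the lexicographically smaller facility id. This
tie rule is applied identically in the test oracles (per-facility
single-source Dijkstra + argmin), which makes agreement checkable exactly —
both computations accumulate costs along the same shortest paths, so even
floating-point sums coincide.

Catchments are node sets, not polygons: no rule is imposed for splitting an
edge at the equidistant interior point, and boundary *edges* (endpoints
labelled differently) are reported instead. The GeoJSON export offers convex
hulls purely as a cartographic convenience. Two stations snapped to the same
node are legal; the dominated one gets an empty catchment and a warning.
Parallel edges are collapsed to their cheapest member for all routing, which
is exact for shortest-path purposes. Stations flagged unavailable keep their
catchment by default (availability is a dispatch-time concern); the
`--active-only` flag excludes them from generation instead.

## Four-phase dispatch

1. **Locate.** Snap the incident to a node, read its catchment label (its
   *home* station). A node in a component with no station is a no-coverage
   error.
2. **Candidate set.** If the home station has a unit, candidates are the home
   plus the available stations of adjacent catchments. If it does not, the
   adjacent available stations are the candidates; if *none* of them has a
   unit, the searched region grows by **nearest-facility iteration**: the
   time-nearest station adjacent to the region searched so far is absorbed,
   one per step, until the frontier's time-nearest member is available.
3. **Rank.** One Dijkstra run rooted at the demand node under the congested
   time weights gives every candidate's travel time (the graph is undirected,
   so station→incident equals incident→station); candidates sort by
   (time, facility_id).
4. **Select.** The head of the ranking, with its route; a phase log records
   each step for audit.

The expansion order in phase 2 matters. A network Voronoi diagram has the
order-k adjacency property: the k-th nearest generator's catchment is always
adjacent to the union of the k−1 nearest catchments (any shortest path to it
last crosses a catchment whose generator is at least as near). Absorbing
frontier facilities in travel-time order therefore enumerates stations in
non-decreasing time from the incident, and the first available one is the
*globally* nearest available unit. A plain hop-based ring expansion does not
have this guarantee — a time-nearer unit can sit two adjacency hops away —
and measurably violates availability monotonicity on random planar networks
(92 of 1500 knock-out sequences in our probe). With nearest-facility
iteration the monotonicity is exact: losing units can never shorten the
response time, because every selection is a minimum over a set that only
shrinks. A hop-based BFS remains as the fallback when no travel times are
supplied to `candidate_set`.

Candidates are filtered to available stations in every branch (an unavailable
neighbour is never rankable), and final ties break by facility id.

## Synthetic scenarios

The fixture generator emits grid, path, star and random planar networks.
Random planar networks scatter nodes uniformly in a box sized for a target
spacing (default 200–250 m, a typical urban block scale), join each node to
its 3 nearest neighbours, and bridge residual components through their
closest node pairs; this yields connected graphs with street-like degree
distributions (mostly 3–5). Congestion is realized as concrete vehicle
counts (count = x · k_max · d_l / 1000 for a target saturation x), so the
weighting code always sees ordinary observations. The `riyadh_like` preset
emulates a metropolitan study setting: ~500 nodes, **30 stations**, mixed
speed limits (30–80 km/h) with some segments unlabeled so the 40 km/h default
is exercised, and a uniform saturation of **0.70** on every edge.

What the generator does *not* emulate: real street geometry (one-way systems,
turn restrictions, grade separation), heterogeneous per-segment jam
densities, time-varying traffic, or spatially correlated congestion. Passing
tests therefore demonstrate the correctness of the algorithms under the
stated model, not calibration against real travel times.

## Problem sizes and determinism

The test suite and the acceptance script run at desk scale: networks of
60–500 nodes, 2–30 stations, tens of fixtures, hundreds of dispatches —
enough for every oracle check to be exhaustive where exhaustiveness is the
point (all-simple-paths enumeration is restricted to ≤ 12-node networks).
Every random draw flows from an explicit seed through `numpy`'s Generator;
identical seeds reproduce identical networks, files and dispatch results, and
the CLI writes JSON with fixed key order and floats rounded to 6 decimals so
reruns are byte-identical. Phase timings are logged to stderr only.

## Known limitations

- Node-anchored demand and stations: an incident in the interior of a long
  edge is attributed to the nearer endpoint.
- Undirected edges only; dual carriageways and one-way streets are merged.
- The travel-time model is static; the saturation level is a scenario
  constant, not a feed.
- Catchment exports are node sets / hulls, not exact network-partition
  polygons.
- Single-unit selection only: no queueing of simultaneous incidents, no
  relocation, no hospital-leg routing.
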