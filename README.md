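# emsroute

Network-Voronoi catchment areas and time-based Dijkstra dispatch for
emergency medical services.

When an ambulance is dispatched, "nearest" should mean *fastest*, not
shortest: in a congested city the length-optimal route is routinely not the
time-optimal one, and a wrong assignment costs minutes. `emsroute` is a small
toolkit for analysts and EMS planners that

1. models the road network as a weighted undirected graph G = (N, L) with
   per-segment lengths, speed limits and traffic attributes;
2. converts traffic into **congestion-adjusted travel times**: a segment of
   length d_l (m) with speed limit s_l (km/h), density k_l = n·1000/d_l
   (veh/km) and jam density k_max is weighted

       t = [ d_l / (1000·s_l) · 3600 ] / (1 − k_l/k_max)   [seconds],

   so an empty road costs its free-flow time and a saturated one diverges
   (the ratio is clamped at 0.95; a literal multiplicative variant is
   available as `as_printed` for comparison);
3. carves the network into **catchments** — a network Voronoi diagram built
   by one multi-source Dijkstra sweep from all station anchors, with
   deterministic lexicographic tie-breaking — plus the catchment adjacency
   graph and boundary edges;
4. answers incidents with a **four-phase selection**: locate the demand
   node's home catchment; build the candidate set from the home and adjacent
   stations honoring unit availability (with a nearest-facility expansion
   when entire neighborhoods are out of units); rank candidates by congested
   travel time with a single demand-rooted Dijkstra; select the fastest unit
   and its route.

Everything runs offline on synthetic or user-supplied networks: a seeded
fixture generator produces grid, path, star and random planar road networks,
including a metropolitan preset (~500 nodes, 30 stations, uniform saturation
0.70, 40 km/h default speed for unlabeled roads).

## Worked example

Build a tiny 3×3 grid city (150 m blocks, three stations, every street at
saturation 0.4), delineate catchments, and dispatch to an incident:

```sh
emsroute make-fixture --kind grid --rows 3 --cols 3 --edge-length 150 \
    --facilities 3 --seed 5 --saturation 0.4 --out-dir demo
emsroute build-catchments --network demo/network.csv \
    --facilities demo/facilities.csv --weight time --out demo/catchments.geojson
emsroute dispatch --network demo/network.csv --facilities demo/facilities.csv \
    --demand "46.7027,24.7013" --out demo/result.json
```

which prints

```
wrote fixture (9 nodes, 12 edges) to demo
wrote catchments for 3 facilities to demo/catchments.geojson
selected p01 at 22.5 s; result in demo/result.json
```

`result.json` holds the full audit trail. The incident snapped to node
`n0102`, whose home catchment belongs to station `p01`; all three stations
had units, so the candidates were `{p00, p01, p02}`, ranked at 22.5 s, 67.5 s
and 67.5 s:

```json
"ranked": [
  {"facility_id": "p01", "source": "home_catchment",     "travel_time_s": 22.5},
  {"facility_id": "p00", "source": "adjacent_catchment", "travel_time_s": 67.5},
  {"facility_id": "p02", "source": "adjacent_catchment", "travel_time_s": 67.5}
],
"costs": {"distance_m": 150.0, "time_s_division": 22.5, "time_s_printed": 8.1}
```

The chosen route is one 150 m block: 13.5 s at free flow, 22.5 s once the
saturation of 0.4 divides the speed down (13.5/0.6), and 8.1 s under the
literal multiplicative variant — the side-by-side that motivates using the
division form for dispatch. Re-running `dispatch` with
`--unavailable p01` forces the home station out and selects the fastest
adjacent unit instead (`"source": "adjacent_catchment"` in the phase log).

The same machinery is importable:

```python
from emsroute import (riyadh_like, time_weights, build_nvd, adjacency,
                      dispatch, DispatchRequest)

fx = riyadh_like(seed=1)                       # 500 nodes, 30 stations, sat 0.70
w = time_weights(fx.network)                   # congested seconds per edge
ca = build_nvd(fx.network, fx.facilities, w)   # network Voronoi diagram
res = dispatch(fx.network, fx.facilities, ca, adjacency(fx.network, ca), w,
               DispatchRequest(*fx.demands[0]))
print(res.selected.facility_id, round(res.selected.travel_time_s, 1))  # p11 195.7
```

Input formats: an edge CSV
(`edge_id,u,v,length_m,speed_kmh,vehicle_count,k_max`, with a sibling
`*_nodes.csv` for coordinates) or a GeoJSON LineString collection; stations
as CSV or Point GeoJSON. OSM ingestion is out of scope — bring your own edge
list.

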