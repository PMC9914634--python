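"""Shared fixtures and independent oracles.

The oracles deliberately avoid the package's own graph plumbing: they go
straight through networkx single-source Dijkstra (per facility) or
exhaustive simple-path enumeration, so that agreement with the package's
multi-source sweep is a real cross-check.
"""

from __future__ import annotations

import networkx as nx
import pytest

from emsroute import (
    Facility,
    FacilitySet,
    FixtureSpec,
    NodeRecord,
    RoadNetwork,
    RoadSegment,
    make_fixture,
    snap_facilities,
)


def multigraph_with_weights(net: RoadNetwork, weights) -> nx.MultiGraph:
    g = nx.MultiGraph()
    g.add_nodes_from(net.nodes)
    for seg in net.edges.values():
        g.add_edge(seg.u, seg.v, key=seg.edge_id, w=weights[seg.edge_id])
    return g


def nvd_oracle(net: RoadNetwork, fs: FacilitySet, weights) -> tuple[dict, dict]:
    """Per-facility single-source Dijkstra argmin with the (cost, id) tie rule."""
    g = multigraph_with_weights(net, weights)
    label: dict[str, str] = {}
    dist: dict[str, float] = {}
    for f in sorted(fs, key=lambda f: f.facility_id):
        lengths = nx.single_source_dijkstra_path_length(g, f.anchor_node, weight="w")
        for node, d in lengths.items():
            if node not in dist or (d, f.facility_id) < (dist[node], label[node]):
                dist[node] = d
                label[node] = f.facility_id
    return label, dist


def brute_force_shortest(net: RoadNetwork, weights, src: str, dst: str) -> float:
    """Minimum cost over ALL simple paths (only viable on tiny networks)."""
    g = multigraph_with_weights(net, weights)
    best = float("inf")
    for path in nx.all_simple_paths(g, src, dst):
        cost = 0.0
        for a, b in zip(path, path[1:]):
            cost += min(d["w"] for d in g[a][b].values())
        best = min(best, cost)
    if src == dst:
        best = 0.0
    return best


def path_network(n: int, length_m: float = 1000.0, speed: float = 36.0) -> RoadNetwork:
    """Chain n0-n1-...; 1 km at 36 km/h per edge = 100 s free-flow each."""
    lat = 24.7
    nodes = [NodeRecord(f"n{i}", 46.7 + i * 0.01, lat) for i in range(n)]
    edges = [
        RoadSegment(f"e{i}", f"n{i}", f"n{i + 1}", length_m, speed)
        for i in range(n - 1)
    ]
    return RoadNetwork(nodes, edges)


def facilities_at(net: RoadNetwork, anchors: dict[str, str]) -> FacilitySet:
    """Facilities placed exactly at named nodes (already snapped)."""
    facs = []
    for fid, node in anchors.items():
        rec = net.nodes[node]
        facs.append(Facility(fid, fid, rec.lon, rec.lat, anchor_node=node))
    return FacilitySet(facs)


@pytest.fixture
def grid3():
    """3x3 grid, 100 m edges, uniform 36 km/h, two stations at corners."""
    fx = make_fixture(
        FixtureSpec(kind="grid", rows=3, cols=3, edge_length_m=100.0, speed_set=(36.0,), facility_count=2, seed=7)
    )
    return fx


@pytest.fixture
def planar_fixture():
    """Mid-size seeded planar network with stations and demand points."""
    return make_fixture(
        FixtureSpec(
            kind="random_planar",
            node_count=120,
            edge_length_m=200.0,
            speed_set=(30.0, 50.0, None),
            congestion=("uniform", 0.0, 0.8),
            facility_count=6,
            demand_count=20,
            seed=11,
        )
    )


def snapped(net, facs):
    return snap_facilities(net, facs)
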