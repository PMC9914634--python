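"""Four-phase nearest-available-unit selection.

Given a built network Voronoi diagram and its catchment adjacency, a
dispatch request is resolved in four phases:

1. *locate* — snap the demand point to a graph node and read off its
   home catchment.
2. *candidate set* — the home facility plus the facilities of adjacent
   catchments, restricted to those with an available unit. If none of
   them has a unit, the search region grows by *nearest-facility
   iteration*: repeatedly absorb the time-nearest facility adjacent to
   the region searched so far and look at the new adjacency frontier,
   until an available facility leads the frontier (or the facility set
   is exhausted). Because the k-th nearest generator of a network
   Voronoi diagram is always adjacent to the union of the k-1 nearest
   catchments, this enumeration visits facilities in non-decreasing
   travel-time order, so the unit it stops at is the globally nearest
   available one. Without travel times the expansion degrades to plain
   breadth-first rings over the catchment adjacency graph.
3. *rank* — congested travel times from the demand node to every
   candidate anchor with one Dijkstra run (the graph is undirected, so
   demand-to-facility equals facility-to-demand), sorted ascending by
   (time, facility_id).
4. *select* — the head of the ranking, with its route.

The selected unit is the time-argmin over the constructed candidate set;
by design it need not be the global argmin over all facilities when the
home unit is out — the fallback searches adjacent catchments first, as
the dispatch doctrine prescribes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import networkx as nx

from .config import FormulaMode
from .errors import ExhaustionError, NetworkValidationError, NoCoverageError
from .nvd import CatchmentAdjacency, CatchmentAssignment, catchment_of
from .road_network import FacilitySet, RoadNetwork, snap_point
from .travel_time import travel_time as edge_travel_time

logger = logging.getLogger(__name__)


@dataclass
class DispatchRequest:
    """An incident: either coordinates to snap, or a graph node directly."""

    demand_lon: Optional[float] = None
    demand_lat: Optional[float] = None
    demand_node: Optional[str] = None
    availability_override: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.demand_node is None and (self.demand_lon is None or self.demand_lat is None):
            raise ValueError("request needs demand_lon/demand_lat or demand_node")


@dataclass
class Candidate:
    facility_id: str
    travel_time_s: float
    path: list[str]  # facility anchor ... demand node
    source: str  # "home_catchment" | "adjacent_catchment"


@dataclass
class DispatchResult:
    selected: Candidate
    ranked: list[Candidate]
    demand_node: str
    phase_log: list[dict]


def _weighted_simple_graph(net: RoadNetwork, weights: Mapping[str, float]) -> nx.Graph:
    """Simple graph with parallel edges collapsed to their cheapest member."""
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for seg in net.edges.values():
        w = weights[seg.edge_id]
        if not w > 0:
            raise NetworkValidationError(f"weight for edge {seg.edge_id!r} must be > 0, got {w}")
        if not g.has_edge(seg.u, seg.v) or w < g[seg.u][seg.v]["w"]:
            g.add_edge(seg.u, seg.v, w=w, edge_id=seg.edge_id)
    return g


def locate(ca: CatchmentAssignment, request: DispatchRequest, net: RoadNetwork) -> tuple[str, str]:
    """Phase 1: demand node and its home (catchment) facility."""
    node = request.demand_node if request.demand_node is not None else snap_point(
        net, request.demand_lon, request.demand_lat
    )
    if node not in net.nodes:
        raise NoCoverageError(f"phase locate: demand node {node!r} is not a network node")
    try:
        home = catchment_of(ca, node)
    except NoCoverageError as exc:
        raise NoCoverageError(f"phase locate: {exc}") from exc
    return node, home


def candidate_set(
    home: str,
    adj: CatchmentAdjacency,
    availability: Mapping[str, int],
    times: Optional[Mapping[str, float]] = None,
) -> set[str]:
    """Phase 2: available facilities in the home and adjacent catchments.

    If neither the home facility nor any adjacent one has a unit, the
    searched region is expanded over the catchment adjacency graph until
    an available facility appears. With ``times`` (facility -> travel
    seconds from the demand node) the expansion absorbs one facility per
    step — the time-nearest member of the current adjacency frontier —
    and stops when that leader is available; the frontier's available
    facilities are then the candidates, and the leader is the globally
    nearest available unit. Without ``times`` the expansion is plain
    breadth-first by adjacency rings, stopping at the first ring that
    contains any available facility.
    """

    def ok(fid: str) -> bool:
        return int(availability.get(fid, 1)) == 1

    neighbors = adj.neighbors.get(home, set())
    if ok(home):
        return {home} | {g for g in neighbors if ok(g)}

    if times is None:
        frontier = set(neighbors)
        visited = {home} | frontier
        while frontier:
            found = {g for g in frontier if ok(g)}
            if found:
                return found
            frontier = {h for g in frontier for h in adj.neighbors.get(g, set())} - visited
            visited |= frontier
        raise ExhaustionError("phase candidate_set: no available facility reachable in the adjacency graph")

    region = {home}
    while True:
        frontier = {h for g in region for h in adj.neighbors.get(g, set())} - region
        if not frontier:
            raise ExhaustionError("phase candidate_set: no available facility reachable in the adjacency graph")
        leader = min(frontier, key=lambda g: (times.get(g, float("inf")), g))
        if ok(leader):
            return {g for g in frontier if ok(g)}
        region.add(leader)


def rank_candidates(
    net: RoadNetwork,
    weights: Mapping[str, float],
    candidates: set[str],
    demand_node: str,
    anchors: Mapping[str, str],
    home: Optional[str] = None,
    _sssp: Optional[tuple[dict, dict]] = None,
) -> list[Candidate]:
    """Phase 3: one demand-rooted Dijkstra, candidates sorted by (time, id).

    Candidates unreachable from the demand node are dropped with a
    warning; if every candidate is unreachable the search is exhausted.
    ``_sssp`` lets callers reuse an already-computed (dist, paths) pair
    from the demand node.
    """
    if not candidates:
        raise ExhaustionError("phase rank: empty candidate set")
    if _sssp is None:
        g = _weighted_simple_graph(net, weights)
        dist, paths = nx.single_source_dijkstra(g, demand_node, weight="w")
    else:
        dist, paths = _sssp
    ranked: list[Candidate] = []
    for fid in sorted(candidates):
        anchor = anchors[fid]
        if anchor not in dist:
            logger.warning("candidate %r (anchor %r) unreachable from demand %r; excluded", fid, anchor, demand_node)
            continue
        ranked.append(
            Candidate(
                facility_id=fid,
                travel_time_s=dist[anchor],
                path=list(reversed(paths[anchor])),
                source="home_catchment" if fid == home else "adjacent_catchment",
            )
        )
    if not ranked:
        raise ExhaustionError("phase rank: all candidates unreachable from the demand node")
    ranked.sort(key=lambda c: (c.travel_time_s, c.facility_id))
    return ranked


def dispatch(
    net: RoadNetwork,
    fs: FacilitySet,
    ca: CatchmentAssignment,
    adj: CatchmentAdjacency,
    weights: Mapping[str, float],
    request: DispatchRequest,
) -> DispatchResult:
    """Run all four phases and return the selected unit with an audit log."""
    availability = {f.facility_id: f.available for f in fs}
    availability.update(request.availability_override)

    demand_node, home = locate(ca, request, net)
    log = [{"phase": "locate", "demand_node": demand_node, "home_facility": home}]

    g = _weighted_simple_graph(net, weights)
    dist, paths = nx.single_source_dijkstra(g, demand_node, weight="w")
    anchors = fs.anchors()
    times = {fid: dist.get(anchor, float("inf")) for fid, anchor in anchors.items()}

    candidates = candidate_set(home, adj, availability, times=times)
    log.append(
        {
            "phase": "candidate_set",
            "home_available": int(availability.get(home, 1)),
            "candidates": sorted(candidates),
        }
    )

    ranked = rank_candidates(net, weights, candidates, demand_node, anchors, home=home, _sssp=(dist, paths))
    log.append(
        {
            "phase": "rank",
            "times_s": {c.facility_id: c.travel_time_s for c in ranked},
        }
    )

    selected = ranked[0]
    log.append({"phase": "select", "facility_id": selected.facility_id, "travel_time_s": selected.travel_time_s})
    return DispatchResult(selected=selected, ranked=ranked, demand_node=demand_node, phase_log=log)


def route_costs(
    net: RoadNetwork,
    path: list[str],
    *,
    clamp_max: float = 0.95,
    default_saturation: float | None = None,
) -> tuple[float, dict[str, float]]:
    """Length-based and time-based cost of one route.

    Returns the summed edge lengths in meters (the classic length-only
    Dijkstra cost) and the summed congested travel times in seconds under
    both formula modes, for side-by-side comparison on the same route.
    Consecutive path nodes must be joined by an edge; among parallel
    edges the one with the smallest congested time is charged.
    """
    by_pair: dict[frozenset, list] = {}
    for seg in net.edges.values():
        by_pair.setdefault(frozenset((seg.u, seg.v)), []).append(seg)
    total_m = 0.0
    totals = {m.value: 0.0 for m in FormulaMode}
    for a, b in zip(path, path[1:]):
        segs = by_pair.get(frozenset((a, b)))
        if not segs:
            raise NetworkValidationError(f"path nodes {a!r} and {b!r} are not adjacent")
        best = min(
            segs,
            key=lambda s: edge_travel_time(
                s, FormulaMode.greenshields_division, clamp_max, default_saturation
            ).t_travel_s,
        )
        total_m += best.length_m
        for m in FormulaMode:
            totals[m.value] += edge_travel_time(best, m, clamp_max, default_saturation).t_travel_s
    return total_m, totals
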