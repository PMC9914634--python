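"""Network Voronoi diagram: catchment assignment and catchment adjacency.

Each facility (generator) seeds one catchment: the set of graph nodes for
which it is the cheapest facility under the chosen edge weights (meters
or congested seconds). Assignment runs a single multi-source Dijkstra
sweep with every generator anchor at cost 0; a node belongs to the
generator that settles it first. Cost ties between generators are broken
by the lexicographically smaller facility_id, which makes the diagram
deterministic and testable against a per-facility single-source oracle.

Two catchments are *adjacent* when at least one road edge joins a node of
one to a node of the other; adjacency drives the dispatch fallback when
the home facility has no unit available.
"""

from __future__ import annotations

import heapq
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

from shapely.geometry import MultiPoint, mapping

from .errors import NetworkValidationError, NoCoverageError
from .road_network import FacilitySet, RoadNetwork

logger = logging.getLogger(__name__)


@dataclass
class CatchmentAssignment:
    """Node -> facility labeling with the cost to the assigned facility."""

    label: dict[str, str]
    dist: dict[str, float]
    weight_kind: str  # "distance_m" | "time_s"
    unreachable: set[str] = field(default_factory=set)


@dataclass
class CatchmentAdjacency:
    """Facility adjacency induced by edges whose endpoints differ in label."""

    neighbors: dict[str, set[str]]
    boundary_edges: set[str]


def _collapsed_adjacency(net: RoadNetwork, weights: Mapping[str, float]) -> dict[str, list[tuple[str, float]]]:
    """node -> [(neighbor, min weight over parallel edges)], validated positive."""
    for eid in net.edges:
        if eid not in weights:
            raise NetworkValidationError(f"no weight supplied for edge {eid!r}")
        if not weights[eid] > 0:
            raise NetworkValidationError(f"weight for edge {eid!r} must be > 0, got {weights[eid]}")
    adj: dict[str, dict[str, float]] = {n: {} for n in net.nodes}
    for seg in net.edges.values():
        w = weights[seg.edge_id]
        for a, b in ((seg.u, seg.v), (seg.v, seg.u)):
            if b not in adj[a] or w < adj[a][b]:
                adj[a][b] = w
    return {n: sorted(nbrs.items()) for n, nbrs in adj.items()}


def build_nvd(
    net: RoadNetwork,
    fs: FacilitySet,
    weights: Mapping[str, float],
    *,
    weight_kind: str = "time_s",
    active_only: bool = False,
) -> CatchmentAssignment:
    """Assign every reachable node to its cheapest facility.

    One Dijkstra sweep seeded with all generator anchors at cost 0. The
    heap is keyed by (cost, facility_id, node): on exact cost ties the
    lexicographically smaller facility_id claims the node. With
    ``active_only`` facilities flagged unavailable are excluded as
    generators (by default they keep their catchment and availability is
    handled at dispatch time).
    """
    generators = [f for f in fs if f.available == 1 or not active_only]
    if not generators:
        raise NetworkValidationError("no facilities to use as generators")
    adj = _collapsed_adjacency(net, weights)

    heap: list[tuple[float, str, str]] = []
    for f in sorted(generators, key=lambda f: f.facility_id):
        if f.anchor_node is None:
            raise NetworkValidationError(f"facility {f.facility_id!r} not snapped to the network")
        heapq.heappush(heap, (0.0, f.facility_id, f.anchor_node))

    label: dict[str, str] = {}
    dist: dict[str, float] = {}
    while heap:
        d, fid, node = heapq.heappop(heap)
        if node in label:
            continue
        label[node] = fid
        dist[node] = d
        for nbr, w in adj[node]:
            if nbr not in label:
                heapq.heappush(heap, (d + w, fid, nbr))

    unreachable = set(net.nodes) - label.keys()
    if unreachable:
        logger.warning("%d nodes unreachable from any facility", len(unreachable))
    return CatchmentAssignment(label=label, dist=dist, weight_kind=weight_kind, unreachable=unreachable)


def adjacency(net: RoadNetwork, ca: CatchmentAssignment) -> CatchmentAdjacency:
    """Facilities joined by at least one cross-label edge, plus those edges."""
    neighbors: dict[str, set[str]] = {fid: set() for fid in set(ca.label.values())}
    boundary: set[str] = set()
    for seg in net.edges.values():
        lu, lv = ca.label.get(seg.u), ca.label.get(seg.v)
        if lu is not None and lv is not None and lu != lv:
            boundary.add(seg.edge_id)
            neighbors[lu].add(lv)
            neighbors[lv].add(lu)
    return CatchmentAdjacency(neighbors=neighbors, boundary_edges=boundary)


def catchment_of(ca: CatchmentAssignment, node: str) -> str:
    """The facility whose catchment contains ``node``."""
    if node in ca.unreachable:
        raise NoCoverageError(f"node {node!r} is not covered by any facility")
    try:
        return ca.label[node]
    except KeyError as exc:
        raise NoCoverageError(f"node {node!r} is not part of the catchment assignment") from exc


def export_catchments(
    net: RoadNetwork,
    ca: CatchmentAssignment,
    path: str | Path,
    *,
    fs: Optional[FacilitySet] = None,
    hulls: bool = False,
) -> dict:
    """Write catchments as GeoJSON: one feature per facility plus boundary edges.

    Each catchment feature carries its labeled nodes as a MultiPoint (or
    their convex hull as a Polygon with ``hulls=True``) and a
    ``node_count`` property; boundary edges are LineStrings. A generator
    with an empty catchment (e.g. dominated after sharing an anchor)
    yields an empty geometry and a warning.
    """
    facility_ids = sorted({f.facility_id for f in fs} if fs is not None else set(ca.label.values()))
    by_facility: dict[str, list[str]] = {fid: [] for fid in facility_ids}
    for node, fid in sorted(ca.label.items()):
        by_facility.setdefault(fid, []).append(node)

    features = []
    for fid in facility_ids:
        nodes = by_facility[fid]
        coords = [(net.nodes[n].lon, net.nodes[n].lat) for n in nodes]
        if not coords:
            logger.warning("facility %r has an empty catchment", fid)
            geometry = {"type": "MultiPoint", "coordinates": []}
        elif hulls:
            geometry = mapping(MultiPoint(coords).convex_hull)
        else:
            geometry = {"type": "MultiPoint", "coordinates": [list(c) for c in coords]}
        features.append(
            {
                "type": "Feature",
                "geometry": geometry,
                "properties": {"kind": "catchment", "facility_id": fid, "node_count": len(nodes)},
            }
        )
    for eid in sorted(adjacency(net, ca).boundary_edges):
        seg = net.edges[eid]
        a, b = net.nodes[seg.u], net.nodes[seg.v]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": [[a.lon, a.lat], [b.lon, b.lat]]},
                "properties": {"kind": "boundary", "edge_id": eid, "labels": sorted({ca.label[seg.u], ca.label[seg.v]})},
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)
    return doc
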