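"""Road-network data model, readers/writers, snapping and connectivity.

The road network is a weighted *undirected* graph G = (N, L): nodes carry
WGS84 lon/lat coordinates, edges (road segments) carry length in meters,
a speed limit in km/h, and optional traffic attributes (vehicle count and
maximum density) used by the travel-time model. EMS stations (facilities)
are snapped onto graph nodes; all routing then happens purely on the graph
using edge lengths or travel times — geometric node distance is used only
for snapping.

Two file dialects are supported:

* ``edge_csv`` — header ``edge_id,u,v,length_m,speed_kmh,vehicle_count,k_max``
  (the last three columns may be empty). Node coordinates live in a sibling
  ``<stem>_nodes.csv`` / ``nodes.csv`` file with header ``node_id,lon,lat``;
  without one the network is topologically usable but cannot snap points.
* ``geojson_lines`` — a FeatureCollection of LineString features with
  properties ``edge_id``, ``u``, ``v``, ``length_m``, ``speed_kmh``,
  ``vehicle_count``, ``k_max``. Missing ``length_m`` is computed from the
  geometry with great-circle arithmetic; endpoints are deduplicated at
  1e-7 degrees.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

import networkx as nx

from .errors import FormatError, NetworkValidationError

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_008.8
#: coordinate dedup tolerance for GeoJSON LineString endpoints, degrees
COORD_DECIMALS = 7


def haversine_m(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance in meters between two WGS84 points."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * math.asin(math.sqrt(a))


@dataclass(frozen=True)
class NodeRecord:
    """A graph node. ``lon``/``lat`` may be None for coordinate-free networks."""

    node_id: str
    lon: Optional[float] = None
    lat: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lon is not None and not -180.0 <= self.lon <= 180.0:
            raise NetworkValidationError(f"node {self.node_id!r}: lon {self.lon} out of [-180, 180]")
        if self.lat is not None and not -90.0 <= self.lat <= 90.0:
            raise NetworkValidationError(f"node {self.node_id!r}: lat {self.lat} out of [-90, 90]")

    @property
    def has_coords(self) -> bool:
        return self.lon is not None and self.lat is not None


@dataclass(frozen=True)
class RoadSegment:
    """An undirected road segment between nodes ``u`` and ``v``.

    ``vehicle_count`` is None when no traffic observation exists for the
    segment (distinct from an observed count of zero): the travel-time
    model may then substitute a scenario-wide saturation level.
    ``speed_source`` records whether the speed limit came from the data
    (``given``) or from the configured network-wide default (``default``).
    """

    edge_id: str
    u: str
    v: str
    length_m: float
    speed_limit_kmh: float
    vehicle_count: Optional[float] = None
    k_max: float = 100.0
    speed_source: str = "given"

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise NetworkValidationError(f"edge {self.edge_id!r}: self-loop at node {self.u!r}")
        if not self.length_m > 0:
            raise NetworkValidationError(f"edge {self.edge_id!r}: length_m must be > 0, got {self.length_m}")
        if not self.speed_limit_kmh > 0:
            raise NetworkValidationError(f"edge {self.edge_id!r}: speed_limit_kmh must be > 0, got {self.speed_limit_kmh}")
        if not self.k_max > 0:
            raise NetworkValidationError(f"edge {self.edge_id!r}: k_max must be > 0, got {self.k_max}")
        if self.vehicle_count is not None and self.vehicle_count < 0:
            raise NetworkValidationError(f"edge {self.edge_id!r}: vehicle_count must be >= 0, got {self.vehicle_count}")
        if self.speed_source not in ("given", "default"):
            raise NetworkValidationError(f"edge {self.edge_id!r}: bad speed_source {self.speed_source!r}")


class RoadNetwork:
    """An undirected multigraph of :class:`NodeRecord` and :class:`RoadSegment`.

    Parallel edges are allowed as long as their ``edge_id`` differ.
    """

    def __init__(self, nodes: Iterable[NodeRecord] = (), edges: Iterable[RoadSegment] = ()):
        self.nodes: dict[str, NodeRecord] = {}
        self.edges: dict[str, RoadSegment] = {}
        self._graph: Optional[nx.MultiGraph] = None
        for n in nodes:
            self.add_node(n)
        for e in edges:
            self.add_edge(e)

    def add_node(self, node: NodeRecord) -> None:
        if node.node_id in self.nodes:
            raise NetworkValidationError(f"duplicate node_id {node.node_id!r}")
        self.nodes[node.node_id] = node
        self._graph = None

    def add_edge(self, seg: RoadSegment) -> None:
        if seg.edge_id in self.edges:
            raise NetworkValidationError(f"duplicate edge_id {seg.edge_id!r}")
        for endpoint in (seg.u, seg.v):
            if endpoint not in self.nodes:
                raise NetworkValidationError(f"edge {seg.edge_id!r}: endpoint {endpoint!r} not a network node")
        self.edges[seg.edge_id] = seg
        self._graph = None

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def has_coords(self) -> bool:
        return all(n.has_coords for n in self.nodes.values())

    def graph(self) -> nx.MultiGraph:
        """The network as a networkx MultiGraph keyed by edge_id (cached)."""
        if self._graph is None:
            g = nx.MultiGraph()
            g.add_nodes_from(self.nodes)
            for seg in self.edges.values():
                g.add_edge(seg.u, seg.v, key=seg.edge_id, length_m=seg.length_m)
            self._graph = g
        return self._graph


@dataclass
class Facility:
    """An EMS station: a generator point of the network Voronoi diagram.

    ``available`` is the unit flag p_j: 1 if an ambulance is stationed and
    free at the facility, 0 otherwise. ``anchor_node`` is filled by
    :func:`snap_facilities`.
    """

    facility_id: str
    name: str
    lon: float
    lat: float
    available: int = 1
    anchor_node: Optional[str] = None

    def __post_init__(self) -> None:
        if self.available not in (0, 1):
            raise NetworkValidationError(f"facility {self.facility_id!r}: available must be 0 or 1")


@dataclass
class FacilitySet:
    """Ordered collection of facilities (the generator set P)."""

    facilities: list[Facility] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for f in self.facilities:
            if f.facility_id in seen:
                raise NetworkValidationError(f"duplicate facility_id {f.facility_id!r}")
            seen.add(f.facility_id)

    def __iter__(self) -> Iterator[Facility]:
        return iter(self.facilities)

    def __len__(self) -> int:
        return len(self.facilities)

    def __getitem__(self, facility_id: str) -> Facility:
        for f in self.facilities:
            if f.facility_id == facility_id:
                return f
        raise KeyError(facility_id)

    def anchors(self) -> dict[str, str]:
        """facility_id -> anchor node, requiring every facility snapped."""
        out = {}
        for f in self.facilities:
            if f.anchor_node is None:
                raise NetworkValidationError(f"facility {f.facility_id!r} not snapped to the network")
            out[f.facility_id] = f.anchor_node
        return out


# ---------------------------------------------------------------------------
# readers / writers


def _parse_float(row: dict, col: str, edge_id: str, required: bool) -> Optional[float]:
    raw = (row.get(col) or "").strip()
    if raw == "":
        if required:
            raise FormatError(f"edge {edge_id!r}: missing required column {col!r}")
        return None
    try:
        return float(raw)
    except ValueError as exc:
        raise FormatError(f"edge {edge_id!r}: column {col!r} is not numeric: {raw!r}") from exc


def _find_nodes_sidecar(path: Path) -> Optional[Path]:
    for cand in (path.with_name(path.stem + "_nodes.csv"), path.with_name("nodes.csv")):
        if cand.exists():
            return cand
    return None


def _read_nodes_csv(path: Path) -> list[NodeRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"node_id", "lon", "lat"} <= set(reader.fieldnames):
            raise FormatError(f"{path}: node file must have header node_id,lon,lat")
        return [NodeRecord(row["node_id"], float(row["lon"]), float(row["lat"])) for row in reader]


def read_network(
    path: str | Path,
    format: str = "edge_csv",
    *,
    nodes_path: str | Path | None = None,
    default_speed_kmh: float = 40.0,
    default_k_max: float = 100.0,
) -> RoadNetwork:
    """Read a road network from ``edge_csv`` or ``geojson_lines``.

    Edges missing a speed limit receive ``default_speed_kmh`` and are
    marked ``speed_source="default"``; a missing maximum density becomes
    ``default_k_max``; a missing vehicle count stays None (no observation).
    """
    path = Path(path)
    if format == "edge_csv":
        return _read_edge_csv(path, nodes_path, default_speed_kmh, default_k_max)
    if format == "geojson_lines":
        return _read_geojson_lines(path, default_speed_kmh, default_k_max)
    raise ValueError(f"unknown network format {format!r}")


def _read_edge_csv(path: Path, nodes_path, default_speed_kmh: float, default_k_max: float) -> RoadNetwork:
    nodes_file = Path(nodes_path) if nodes_path is not None else _find_nodes_sidecar(path)
    coord_nodes = {n.node_id: n for n in _read_nodes_csv(nodes_file)} if nodes_file else {}

    net = RoadNetwork()
    segs: list[RoadSegment] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"edge_id", "u", "v", "length_m"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(f"{path}: edge file must have columns {sorted(required)}; got {reader.fieldnames}")
        for i, row in enumerate(reader):
            edge_id = (row.get("edge_id") or "").strip() or f"row{i}"
            u, v = (row.get("u") or "").strip(), (row.get("v") or "").strip()
            if not u or not v:
                raise FormatError(f"edge {edge_id!r}: empty endpoint id")
            length = _parse_float(row, "length_m", edge_id, required=True)
            speed = _parse_float(row, "speed_kmh", edge_id, required=False)
            count = _parse_float(row, "vehicle_count", edge_id, required=False)
            k_max = _parse_float(row, "k_max", edge_id, required=False)
            segs.append(
                RoadSegment(
                    edge_id=edge_id,
                    u=u,
                    v=v,
                    length_m=length,
                    speed_limit_kmh=speed if speed is not None else default_speed_kmh,
                    vehicle_count=count,
                    k_max=k_max if k_max is not None else default_k_max,
                    speed_source="given" if speed is not None else "default",
                )
            )
    for seg in segs:
        for endpoint in (seg.u, seg.v):
            if endpoint not in net.nodes:
                net.add_node(coord_nodes.get(endpoint, NodeRecord(endpoint)))
    for seg in segs:
        net.add_edge(seg)
    return net


def _read_geojson_lines(path: Path, default_speed_kmh: float, default_k_max: float) -> RoadNetwork:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")

    net = RoadNetwork()
    key_to_id: dict[tuple[float, float], str] = {}

    def node_for(coord: list[float], declared: Optional[str]) -> str:
        lon, lat = round(coord[0], COORD_DECIMALS), round(coord[1], COORD_DECIMALS)
        key = (lon, lat)
        if key not in key_to_id:
            node_id = declared if declared is not None else f"n{len(key_to_id)}"
            key_to_id[key] = node_id
            net.add_node(NodeRecord(node_id, lon, lat))
        return key_to_id[key]

    for i, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "LineString" or len(geom.get("coordinates", [])) < 2:
            raise FormatError(f"feature {i}: geometry must be a LineString with >= 2 coordinates")
        coords = geom["coordinates"]
        props = feat.get("properties") or {}
        edge_id = str(props.get("edge_id", f"e{i}"))
        length = props.get("length_m")
        if length is None:
            length = sum(
                haversine_m(coords[j][0], coords[j][1], coords[j + 1][0], coords[j + 1][1])
                for j in range(len(coords) - 1)
            )
        speed = props.get("speed_kmh")
        net.add_edge(
            RoadSegment(
                edge_id=edge_id,
                u=node_for(coords[0], props.get("u")),
                v=node_for(coords[-1], props.get("v")),
                length_m=float(length),
                speed_limit_kmh=float(speed) if speed is not None else default_speed_kmh,
                vehicle_count=None if props.get("vehicle_count") is None else float(props["vehicle_count"]),
                k_max=float(props.get("k_max", default_k_max)),
                speed_source="given" if speed is not None else "default",
            )
        )
    return net


def write_network(net: RoadNetwork, path: str | Path, format: str = "edge_csv") -> None:
    """Write a network so that :func:`read_network` re-reads it losslessly.

    Default-sourced speeds are written as empty/null so the reader
    re-derives ``speed_source`` faithfully.
    """
    path = Path(path)
    if format == "edge_csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["edge_id", "u", "v", "length_m", "speed_kmh", "vehicle_count", "k_max"])
            for seg in net.edges.values():
                w.writerow(
                    [
                        seg.edge_id,
                        seg.u,
                        seg.v,
                        repr(seg.length_m),
                        repr(seg.speed_limit_kmh) if seg.speed_source == "given" else "",
                        "" if seg.vehicle_count is None else repr(seg.vehicle_count),
                        repr(seg.k_max),
                    ]
                )
        if net.has_coords:
            with open(path.with_name(path.stem + "_nodes.csv"), "w", newline="", encoding="utf-8") as fh:
                w = csv.writer(fh)
                w.writerow(["node_id", "lon", "lat"])
                for n in net.nodes.values():
                    w.writerow([n.node_id, repr(n.lon), repr(n.lat)])
    elif format == "geojson_lines":
        feats = []
        for seg in net.edges.values():
            a, b = net.nodes[seg.u], net.nodes[seg.v]
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "LineString", "coordinates": [[a.lon, a.lat], [b.lon, b.lat]]},
                    "properties": {
                        "edge_id": seg.edge_id,
                        "u": seg.u,
                        "v": seg.v,
                        "length_m": seg.length_m,
                        "speed_kmh": seg.speed_limit_kmh if seg.speed_source == "given" else None,
                        "vehicle_count": seg.vehicle_count,
                        "k_max": seg.k_max,
                    },
                }
            )
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_facilities(path: str | Path) -> FacilitySet:
    """Read facilities from CSV ``facility_id,name,lon,lat,available`` or Point GeoJSON."""
    path = Path(path)
    facs: list[Facility] = []
    if path.suffix.lower() == ".csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            need = {"facility_id", "name", "lon", "lat", "available"}
            if reader.fieldnames is None or not need <= set(reader.fieldnames):
                raise FormatError(f"{path}: facility file must have columns {sorted(need)}")
            for row in reader:
                facs.append(
                    Facility(
                        facility_id=row["facility_id"],
                        name=row["name"],
                        lon=float(row["lon"]),
                        lat=float(row["lat"]),
                        available=int(row["available"]),
                    )
                )
    else:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        for i, feat in enumerate(doc.get("features", [])):
            geom = feat.get("geometry") or {}
            if geom.get("type") != "Point":
                raise FormatError(f"feature {i}: facility geometry must be a Point")
            props = feat.get("properties") or {}
            facs.append(
                Facility(
                    facility_id=str(props.get("facility_id", f"p{i}")),
                    name=str(props.get("name", "")),
                    lon=float(geom["coordinates"][0]),
                    lat=float(geom["coordinates"][1]),
                    available=int(props.get("available", 1)),
                )
            )
    return FacilitySet(facs)


def write_facilities(fs: FacilitySet, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["facility_id", "name", "lon", "lat", "available"])
        for f in fs:
            w.writerow([f.facility_id, f.name, repr(f.lon), repr(f.lat), f.available])


# ---------------------------------------------------------------------------
# snapping and connectivity


def snap_point(net: RoadNetwork, lon: float, lat: float) -> str:
    """Nearest node to (lon, lat) by great-circle distance.

    Ties are broken by the lexicographically smallest node_id so that
    snapping is deterministic.
    """
    if not net.nodes:
        raise NetworkValidationError("cannot snap to an empty network")
    if not net.has_coords:
        raise NetworkValidationError("network has coordinate-free nodes; snapping unavailable")
    best = min(
        ((haversine_m(lon, lat, n.lon, n.lat), n.node_id) for n in net.nodes.values()),
    )
    return best[1]


def snap_facilities(net: RoadNetwork, fs: FacilitySet) -> FacilitySet:
    """Anchor every facility to its nearest network node (P ⊂ N).

    Facilities sharing an anchor are legal but logged as a warning: the
    catchment of the dominated generator will be empty under the
    lexicographic tie rule.
    """
    snapped: list[Facility] = []
    seen: dict[str, str] = {}
    for f in fs:
        anchor = snap_point(net, f.lon, f.lat)
        if anchor in seen:
            logger.warning(
                "facilities %r and %r share anchor node %r", seen[anchor], f.facility_id, anchor
            )
        else:
            seen[anchor] = f.facility_id
        snapped.append(replace(f, anchor_node=anchor))
    return FacilitySet(snapped)


def connected_components(net: RoadNetwork) -> list[set[str]]:
    """Connected components as node-id sets, largest first (ties by min id)."""
    comps = [set(c) for c in nx.connected_components(net.graph())]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps
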