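"""Seeded synthetic road networks, stations and incidents.

Every module of the package is testable offline: this generator emits
deterministic grid, path, star and random planar networks with
configurable edge lengths, speed limits (including unlabeled edges that
exercise the network-wide default speed) and congestion levels, plus a
seeded draw of facility nodes and demand points.

Random planar networks are built by scattering nodes uniformly in a
small box, joining each to its k nearest neighbors and then bridging
remaining components through their closest node pairs — a cheap stand-in
with street-network-like degree distributions. The ``riyadh_like``
preset emulates a metropolitan study setting: ~500 nodes, 30 EMS
stations, mixed speed limits with some unlabeled (defaulting to
40 km/h), and a uniform saturation level of 0.70 on every edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .road_network import (
    Facility,
    FacilitySet,
    NodeRecord,
    RoadNetwork,
    RoadSegment,
    connected_components,
    haversine_m,
    snap_facilities,
)

# base point of the synthetic coordinate frame (central Arabian plateau)
BASE_LON, BASE_LAT = 46.70, 24.70
_M_PER_DEG_LAT = 111_320.0


def _offset(lon: float, lat: float, dx_m: float, dy_m: float) -> tuple[float, float]:
    """Shift a WGS84 point by meters east (dx) and north (dy), small-offset approx."""
    return (
        lon + dx_m / (_M_PER_DEG_LAT * math.cos(math.radians(lat))),
        lat + dy_m / _M_PER_DEG_LAT,
    )


@dataclass
class FixtureSpec:
    """Everything that determines a synthetic scenario; the seed fixes it all.

    ``congestion`` is either ``None`` (no traffic observations: every
    ``vehicle_count`` stays None), ``("constant", s)`` for a uniform
    saturation ratio s on every edge, or ``("uniform", lo, hi)`` for a
    per-edge ratio drawn uniformly. Ratios are realized as concrete
    vehicle counts (count = s * k_max * length / 1000) so the weighting
    code sees ordinary observations. ``speed_set`` entries may be None:
    those edges are emitted without a speed limit and pick up the
    configured default at read/weight time.
    """

    kind: str = "grid"  # grid | random_planar | path | star
    rows: int = 4
    cols: int = 4
    node_count: int = 50
    edge_length_m: float | tuple[float, float] = 200.0
    speed_set: Sequence[Optional[float]] = (40.0,)
    congestion: Optional[tuple] = None
    k_max: float = 100.0
    facility_count: int = 2
    demand_count: int = 20
    seed: int = 0
    default_speed_kmh: float = 40.0
    k_nearest: int = 3
    allow_disconnected: bool = False


@dataclass
class Fixture:
    network: RoadNetwork
    facilities: FacilitySet
    demands: list[tuple[float, float]] = field(default_factory=list)
    spec: Optional[FixtureSpec] = None


def _edge_length(spec: FixtureSpec, rng: np.random.Generator) -> float:
    if isinstance(spec.edge_length_m, tuple):
        lo, hi = spec.edge_length_m
        return float(rng.uniform(lo, hi))
    return float(spec.edge_length_m)


def _make_segment(spec: FixtureSpec, rng: np.random.Generator, edge_id: str, u: str, v: str, length: float) -> RoadSegment:
    speed = spec.speed_set[int(rng.integers(len(spec.speed_set)))]
    if spec.congestion is None:
        count = None
    elif spec.congestion[0] == "constant":
        count = spec.congestion[1] * spec.k_max * length / 1000.0
    elif spec.congestion[0] == "uniform":
        count = float(rng.uniform(spec.congestion[1], spec.congestion[2])) * spec.k_max * length / 1000.0
    else:
        raise ValueError(f"unknown congestion sampler {spec.congestion!r}")
    return RoadSegment(
        edge_id=edge_id,
        u=u,
        v=v,
        length_m=length,
        speed_limit_kmh=speed if speed is not None else spec.default_speed_kmh,
        vehicle_count=count,
        k_max=spec.k_max,
        speed_source="given" if speed is not None else "default",
    )


def _grid(spec: FixtureSpec, rng: np.random.Generator) -> RoadNetwork:
    net = RoadNetwork()
    step = spec.edge_length_m if not isinstance(spec.edge_length_m, tuple) else sum(spec.edge_length_m) / 2
    for r in range(spec.rows):
        for c in range(spec.cols):
            lon, lat = _offset(BASE_LON, BASE_LAT, c * step, r * step)
            net.add_node(NodeRecord(f"n{r:02d}{c:02d}", lon, lat))
    k = 0
    for r in range(spec.rows):
        for c in range(spec.cols):
            if c + 1 < spec.cols:
                net.add_edge(_make_segment(spec, rng, f"e{k:04d}", f"n{r:02d}{c:02d}", f"n{r:02d}{c + 1:02d}", _edge_length(spec, rng)))
                k += 1
            if r + 1 < spec.rows:
                net.add_edge(_make_segment(spec, rng, f"e{k:04d}", f"n{r:02d}{c:02d}", f"n{r + 1:02d}{c:02d}", _edge_length(spec, rng)))
                k += 1
    return net


def _path(spec: FixtureSpec, rng: np.random.Generator) -> RoadNetwork:
    net = RoadNetwork()
    step = spec.edge_length_m if not isinstance(spec.edge_length_m, tuple) else sum(spec.edge_length_m) / 2
    for i in range(spec.node_count):
        lon, lat = _offset(BASE_LON, BASE_LAT, i * step, 0.0)
        net.add_node(NodeRecord(f"n{i:03d}", lon, lat))
    for i in range(spec.node_count - 1):
        net.add_edge(_make_segment(spec, rng, f"e{i:04d}", f"n{i:03d}", f"n{i + 1:03d}", _edge_length(spec, rng)))
    return net


def _star(spec: FixtureSpec, rng: np.random.Generator) -> RoadNetwork:
    net = RoadNetwork()
    net.add_node(NodeRecord("n000", BASE_LON, BASE_LAT))
    step = spec.edge_length_m if not isinstance(spec.edge_length_m, tuple) else sum(spec.edge_length_m) / 2
    leaves = spec.node_count - 1
    for i in range(leaves):
        theta = 2 * math.pi * i / leaves
        lon, lat = _offset(BASE_LON, BASE_LAT, step * math.cos(theta), step * math.sin(theta))
        net.add_node(NodeRecord(f"n{i + 1:03d}", lon, lat))
        net.add_edge(_make_segment(spec, rng, f"e{i:04d}", "n000", f"n{i + 1:03d}", _edge_length(spec, rng)))
    return net


def _random_planar(spec: FixtureSpec, rng: np.random.Generator) -> RoadNetwork:
    n = spec.node_count
    spacing = spec.edge_length_m if not isinstance(spec.edge_length_m, tuple) else sum(spec.edge_length_m) / 2
    side = max(1.0, math.sqrt(n)) * spacing
    xs = rng.uniform(0.0, side, size=n)
    ys = rng.uniform(0.0, side, size=n)
    net = RoadNetwork()
    coords = []
    for i in range(n):
        lon, lat = _offset(BASE_LON, BASE_LAT, float(xs[i]), float(ys[i]))
        net.add_node(NodeRecord(f"n{i:04d}", lon, lat))
        coords.append((lon, lat))

    # join each node to its k nearest neighbors (planar-ish, street-like degrees)
    dx = xs[:, None] - xs[None, :]
    dy = ys[:, None] - ys[None, :]
    d2 = dx * dx + dy * dy
    np.fill_diagonal(d2, np.inf)
    pairs: set[tuple[int, int]] = set()
    k = min(spec.k_nearest, n - 1)
    order = np.argsort(d2, axis=1)
    for i in range(n):
        for j in order[i, :k]:
            pairs.add((min(i, int(j)), max(i, int(j))))

    edges = []
    for idx, (i, j) in enumerate(sorted(pairs)):
        length = haversine_m(*coords[i], *coords[j])
        edges.append((f"e{idx:04d}", f"n{i:04d}", f"n{j:04d}", max(length, 1.0)))
    for eid, u, v, length in edges:
        net.add_edge(_make_segment(spec, rng, eid, u, v, length))

    if not spec.allow_disconnected:
        comps = connected_components(net)
        extra = 0
        while len(comps) > 1:
            main, rest = comps[0], comps[1]
            best = None
            for a in sorted(main):
                ia = int(a[1:])
                for b in sorted(rest):
                    ib = int(b[1:])
                    d = d2[ia, ib]
                    if best is None or d < best[0]:
                        best = (d, a, b)
            _, a, b = best
            length = max(haversine_m(*coords[int(a[1:])], *coords[int(b[1:])]), 1.0)
            net.add_edge(_make_segment(spec, rng, f"bridge{extra:03d}", a, b, length))
            extra += 1
            comps = connected_components(net)
    return net


_BUILDERS = {"grid": _grid, "path": _path, "star": _star, "random_planar": _random_planar}


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Deterministic network + snapped facilities + demand points for a seed."""
    if spec.kind not in _BUILDERS:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    rng = np.random.default_rng(spec.seed)
    net = _BUILDERS[spec.kind](spec, rng)
    if spec.facility_count > len(net.nodes):
        raise ValueError(f"facility_count {spec.facility_count} exceeds node count {len(net.nodes)}")

    node_ids = sorted(net.nodes)
    chosen = rng.choice(len(node_ids), size=spec.facility_count, replace=False)
    facilities = []
    for rank, idx in enumerate(sorted(int(i) for i in chosen)):
        node = net.nodes[node_ids[idx]]
        facilities.append(
            Facility(facility_id=f"p{rank:02d}", name=f"Station {rank}", lon=node.lon, lat=node.lat)
        )
    fs = snap_facilities(net, FacilitySet(facilities))

    demands = []
    for _ in range(spec.demand_count):
        node = net.nodes[node_ids[int(rng.integers(len(node_ids)))]]
        jlon, jlat = _offset(node.lon, node.lat, float(rng.uniform(-30, 30)), float(rng.uniform(-30, 30)))
        demands.append((jlon, jlat))
    return Fixture(network=net, facilities=fs, demands=demands, spec=spec)


def riyadh_like(seed: int = 0) -> Fixture:
    """Metropolitan-scale preset: ~500 nodes, 30 stations, saturation 0.70.

    Speed limits mix arterial and local values with some edges unlabeled
    so the 40 km/h network default is exercised; every edge carries a
    vehicle count realizing a uniform saturation ratio of 0.70.
    """
    spec = FixtureSpec(
        kind="random_planar",
        node_count=500,
        edge_length_m=250.0,
        speed_set=(30.0, 50.0, 60.0, 80.0, None),
        congestion=("constant", 0.70),
        k_max=100.0,
        facility_count=30,
        demand_count=50,
        seed=seed,
        default_speed_kmh=40.0,
    )
    return make_fixture(spec)
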