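"""Congestion-adjusted edge travel times (the TDRA edge-weight model).

A segment of length d_l meters with speed limit s_l km/h has free-flow
traversal time

    t_free = d_l / (1000 * s_l) * 3600   [seconds].

Observed traffic enters through the density k_l = n * 1000 / d_l
(vehicles per km, n vehicles occupying the segment) and the saturation
ratio k_l / k_max in [0, 1): 0 is an empty road, 1 is jam density. The
congested traversal time is, in the default ``greenshields_division``
mode,

    t = t_free / (1 - k_l / k_max),

which grows without bound as the road saturates (the ratio is clamped at
``clamp_max``, default 0.95, to keep weights finite — near jam density
flow is erratic and the model is not meant to be evaluated there). The
alternative ``as_printed`` mode instead multiplies by (1 - k_l / k_max);
see :class:`~emsroute.config.FormulaMode` for why both exist. Both modes
reduce exactly to t_free on an empty road.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import FormulaMode
from .errors import DomainError
from .road_network import RoadNetwork, RoadSegment

DEFAULT_CLAMP = 0.95


def free_flow_time(length_m: float, speed_kmh: float) -> float:
    """Seconds to traverse ``length_m`` at a constant ``speed_kmh``."""
    if not length_m > 0:
        raise DomainError(f"length_m must be > 0, got {length_m}")
    if not speed_kmh > 0:
        raise DomainError(f"speed_kmh must be > 0, got {speed_kmh}")
    return length_m / (1000.0 * speed_kmh) * 3600.0


def traffic_density(vehicle_count: float, length_m: float) -> float:
    """Vehicles per km: ``vehicle_count`` vehicles occupying ``length_m`` meters."""
    if not length_m > 0:
        raise DomainError(f"length_m must be > 0, got {length_m}")
    if vehicle_count < 0:
        raise DomainError(f"vehicle_count must be >= 0, got {vehicle_count}")
    return vehicle_count * 1000.0 / length_m


def saturation_ratio(density: float, k_max: float, clamp_max: float = DEFAULT_CLAMP) -> float:
    """density / k_max, clamped into [0, clamp_max] to keep weights finite."""
    if not k_max > 0:
        raise DomainError(f"k_max must be > 0, got {k_max}")
    if density < 0:
        raise DomainError(f"density must be >= 0, got {density}")
    return min(density / k_max, clamp_max)


@dataclass(frozen=True)
class EdgeWeights:
    """Per-edge quantities of the travel-time model (units in field names)."""

    edge_id: str
    t_free_s: float
    density_veh_per_km: float
    saturation_ratio: float
    t_travel_s: float
    formula_mode: FormulaMode


def travel_time(
    segment: RoadSegment,
    mode: FormulaMode | str = FormulaMode.greenshields_division,
    clamp_max: float = DEFAULT_CLAMP,
    default_saturation: float | None = None,
) -> EdgeWeights:
    """Congestion-adjusted traversal time for one segment.

    When the segment carries no vehicle-count observation,
    ``default_saturation`` (if given) supplies a scenario-wide saturation
    ratio; otherwise the segment is treated as free-flowing.
    """
    mode = FormulaMode(mode)
    t_free = free_flow_time(segment.length_m, segment.speed_limit_kmh)
    if segment.vehicle_count is None and default_saturation is not None:
        ratio = min(default_saturation, clamp_max)
        density = ratio * segment.k_max
    else:
        density = traffic_density(segment.vehicle_count or 0.0, segment.length_m)
        ratio = saturation_ratio(density, segment.k_max, clamp_max)
    if mode is FormulaMode.greenshields_division:
        t = t_free / (1.0 - ratio)
    else:
        t = t_free * (1.0 - ratio)
    return EdgeWeights(
        edge_id=segment.edge_id,
        t_free_s=t_free,
        density_veh_per_km=density,
        saturation_ratio=ratio,
        t_travel_s=t,
        formula_mode=mode,
    )


def weight_all_edges(
    net: RoadNetwork,
    mode: FormulaMode | str = FormulaMode.greenshields_division,
    clamp_max: float = DEFAULT_CLAMP,
    default_saturation: float | None = None,
) -> dict[str, EdgeWeights]:
    """Travel-time weights for every edge of the network (deterministic)."""
    return {
        eid: travel_time(seg, mode, clamp_max, default_saturation)
        for eid, seg in net.edges.items()
    }


def time_weights(
    net: RoadNetwork,
    mode: FormulaMode | str = FormulaMode.greenshields_division,
    clamp_max: float = DEFAULT_CLAMP,
    default_saturation: float | None = None,
) -> dict[str, float]:
    """edge_id -> congested traversal time in seconds (routing weights)."""
    return {
        eid: ew.t_travel_s
        for eid, ew in weight_all_edges(net, mode, clamp_max, default_saturation).items()
    }


def distance_weights(net: RoadNetwork) -> dict[str, float]:
    """edge_id -> length in meters (classic length-only routing weights)."""
    return {eid: seg.length_m for eid, seg in net.edges.items()}
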