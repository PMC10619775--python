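"""Facility service areas and block-group catchment membership.

A facility's T-minute catchment is the set of block groups whose centroid
can be reached from the facility within T drive minutes on the road
network.  Reachability is evaluated directly as network travel time from
the facility's snap node to the centroid's snap node; this is equivalent to
building an explicit isochrone polygon and testing centroid containment,
without polygonization artifacts.  The boundary is inclusive: a travel time
of exactly T minutes counts as inside.

Zero-population block groups are excluded from every catchment and from all
downstream accounting — there is no population there requiring access.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .network import RoadNetwork, snap, travel_times_from

__all__ = ["Facility", "BlockGroup", "CatchmentIndex", "build_catchments", "no_access_set"]


@dataclass(frozen=True)
class Facility:
    """An ICU location with its adult intensive-care bed count."""

    id: str
    x_km: float
    y_km: float
    adult_icu_beds: int
    region_code: str

    def __post_init__(self):
        if self.adult_icu_beds < 1:
            raise ValueError(
                f"facility {self.id!r}: adult_icu_beds must be >= 1, got {self.adult_icu_beds}"
            )

    @property
    def location(self) -> tuple[float, float]:
        return (self.x_km, self.y_km)


@dataclass
class BlockGroup:
    """A population unit: total adults (>=15 y) and per-group adult counts.

    ``geometry`` may be a Point or a Polygon; the centroid used for
    catchment membership is the geometric centroid of the polygon (even if
    it falls outside the polygon — no containment correction is applied).
    """

    id: str
    geometry: BaseGeometry
    pop_total: int
    pop_by_group: dict[str, int]
    urbanization: str
    region_code: str

    def __post_init__(self):
        if self.pop_total < 0:
            raise ValueError(f"block group {self.id!r}: pop_total must be >= 0")
        for g, n in self.pop_by_group.items():
            if n < 0:
                raise ValueError(f"block group {self.id!r}: pop_{g} must be >= 0")

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.geometry if isinstance(self.geometry, Point) else self.geometry.centroid
        return (c.x, c.y)

    @property
    def populated(self) -> bool:
        return self.pop_total > 0


@dataclass
class CatchmentIndex:
    """Bidirectional facility/block-group reachability at one threshold.

    ``served[i]`` is the set of populated block-group ids within
    ``threshold_minutes`` of facility ``i``; ``accessible[j]`` is the
    mirror image.  ``served_population[i]`` is the summed adult population
    of the facility's catchment — its "population served".
    ``travel_minutes[(i, j)]`` records the drive time for every pair in
    the index.
    """

    threshold_minutes: float
    served: dict[str, set[str]] = field(default_factory=dict)
    accessible: dict[str, set[str]] = field(default_factory=dict)
    served_population: dict[str, int] = field(default_factory=dict)
    travel_minutes: dict[tuple[str, str], float] = field(default_factory=dict)


def build_catchments(
    network: RoadNetwork,
    facilities: list[Facility],
    block_groups: list[BlockGroup],
    threshold_minutes: float,
    snap_walk_speed_kmh: float | None = None,
) -> CatchmentIndex:
    """Build the T-minute catchment index for all facilities at once.

    One Dijkstra pass per facility from its snap node.  If
    ``snap_walk_speed_kmh`` is given, both snap legs (facility to its node,
    centroid to its node) are charged at that speed; by default they cost
    zero minutes.

    Block groups with zero population never enter the index.
    """
    if threshold_minutes <= 0:
        raise ValueError(f"threshold_minutes must be > 0, got {threshold_minutes}")

    populated = [bg for bg in block_groups if bg.populated]
    bg_snaps = {bg.id: snap(network, bg.centroid) for bg in populated}
    pop = {bg.id: bg.pop_total for bg in populated}

    index = CatchmentIndex(threshold_minutes=float(threshold_minutes))
    index.accessible = {bg.id: set() for bg in populated}

    for fac in facilities:
        fac_snap = snap(network, fac.location)
        times = travel_times_from(network, fac_snap.node_id)
        fac_penalty = (
            60.0 * fac_snap.snap_km / snap_walk_speed_kmh if snap_walk_speed_kmh else 0.0
        )
        served: set[str] = set()
        for bg in populated:
            s = bg_snaps[bg.id]
            if s.node_id not in times:
                continue
            t = times[s.node_id] + fac_penalty
            if snap_walk_speed_kmh:
                t += 60.0 * s.snap_km / snap_walk_speed_kmh
            if t <= threshold_minutes:
                served.add(bg.id)
                index.accessible[bg.id].add(fac.id)
                index.travel_minutes[(fac.id, bg.id)] = t
        index.served[fac.id] = served
        index.served_population[fac.id] = sum(pop[j] for j in served)

    return index


def no_access_set(index: CatchmentIndex, block_groups: list[BlockGroup]) -> set[str]:
    """Populated block groups whose centroid lies outside every catchment."""
    return {
        bg.id
        for bg in block_groups
        if bg.populated and not index.accessible.get(bg.id)
    }
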