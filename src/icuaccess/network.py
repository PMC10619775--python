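"""Travel-time computation on a planar road network.

The road network is an undirected weighted graph: nodes carry planar
coordinates in kilometres, edges carry a physical length (km) and a speed
limit (km/h).  The traversal cost of an edge is its drive time in minutes,

    minutes = 60 * length_km / speed_kmh

which is the only travel-related factor modelled here: capacity, stoplights
and turn penalties that commercial routing engines incorporate are
deliberately out of scope.  Off-network points (facilities, block-group
centroids) are attached to the graph by snapping to the nearest node; by
default the snap leg contributes zero minutes, optionally it can be charged
at a configurable walk speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = ["RoadNetwork", "SnapResult", "travel_times_from", "snap"]


def edge_minutes(length_km: float, speed_kmh: float) -> float:
    """Drive time of a single edge in minutes."""
    if length_km <= 0:
        raise ValueError(f"edge length must be > 0, got {length_km}")
    if speed_kmh <= 0:
        raise ValueError(f"edge speed must be > 0, got {speed_kmh}")
    return 60.0 * length_km / speed_kmh


@dataclass
class RoadNetwork:
    """Undirected road graph with planar node coordinates in km.

    ``graph`` edges carry ``length_km``, ``speed_kmh`` and the derived
    ``minutes`` attribute.  The graph may be disconnected; unreachable
    nodes simply never appear in travel-time maps.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def add_node(self, node_id, x_km: float, y_km: float) -> None:
        self.graph.add_node(node_id, x=float(x_km), y=float(y_km))

    def add_edge(self, u, v, length_km: float, speed_kmh: float) -> None:
        minutes = edge_minutes(length_km, speed_kmh)
        self.graph.add_edge(
            u, v, length_km=float(length_km), speed_kmh=float(speed_kmh), minutes=minutes
        )

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def coords(self, node_id) -> tuple[float, float]:
        data = self.graph.nodes[node_id]
        return data["x"], data["y"]

    def node_array(self) -> tuple[list, np.ndarray]:
        """Node ids (sorted) and matching (n, 2) coordinate array."""
        ids = sorted(self.graph.nodes)
        xy = np.array([[self.graph.nodes[i]["x"], self.graph.nodes[i]["y"]] for i in ids])
        return ids, xy


@dataclass(frozen=True)
class SnapResult:
    """Nearest-node attachment of an off-network point."""

    point: tuple[float, float]
    node_id: object
    snap_km: float


def travel_times_from(network: RoadNetwork, source_node) -> dict:
    """Single-source shortest-path drive times in minutes.

    Returns a mapping node id -> minutes for every node reachable from
    ``source_node``; unreachable nodes are absent.  Dijkstra on the
    ``minutes`` edge weight (all weights are positive by construction).
    """
    if source_node not in network.graph:
        raise KeyError(f"unknown node id: {source_node!r}")
    return dict(
        nx.single_source_dijkstra_path_length(network.graph, source_node, weight="minutes")
    )


def snap(network: RoadNetwork, point: tuple[float, float]) -> SnapResult:
    """Snap a planar point to the nearest network node.

    Ties in Euclidean distance are broken by the smallest node id so the
    result is deterministic regardless of node insertion order.
    """
    if network.n_nodes == 0:
        raise ValueError("cannot snap to an empty network")
    ids, xy = network.node_array()
    px, py = float(point[0]), float(point[1])
    d2 = (xy[:, 0] - px) ** 2 + (xy[:, 1] - py) ** 2
    best = int(np.argmin(d2))  # ids sorted ascending -> argmin's first hit is smallest id
    return SnapResult(point=(px, py), node_id=ids[best], snap_km=float(np.sqrt(d2[best])))
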