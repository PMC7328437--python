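"""Routing and movement on the street network.

Agents travel along shortest paths (A* with a Euclidean heuristic, which is
admissible because edge lengths are at least the Euclidean distance between
their endpoints) at a constant walking speed, advancing in discrete steps.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

from .environment import RoadNetwork

__all__ = ["Route", "shortest_path", "advance", "PathCache", "RoutingError"]


class RoutingError(RuntimeError):
    """Origin and destination are not connected (impossible in a valid town)."""


@dataclass
class Route:
    """An ordered node path with arc-length bookkeeping."""

    nodes: list[int]
    points: np.ndarray            # (m, 2) node coordinates
    cum_lengths: np.ndarray       # (m,) cumulative arc length, cum[0] == 0
    traversed: float = 0.0
    expansions: int = 0           # A* node expansions (diagnostics)

    @property
    def total_length(self) -> float:
        return float(self.cum_lengths[-1])

    @property
    def arrived(self) -> bool:
        return self.traversed >= self.total_length

    def position_at(self, arc: float) -> tuple[float, float]:
        """Interpolated position at a given arc length along the route."""
        arc = min(max(arc, 0.0), self.total_length)
        i = int(np.searchsorted(self.cum_lengths, arc, side="right")) - 1
        i = min(i, len(self.nodes) - 2) if len(self.nodes) > 1 else 0
        if len(self.nodes) == 1:
            return tuple(self.points[0])
        seg = self.cum_lengths[i + 1] - self.cum_lengths[i]
        f = 0.0 if seg == 0 else (arc - self.cum_lengths[i]) / seg
        p = self.points[i] + f * (self.points[i + 1] - self.points[i])
        return (float(p[0]), float(p[1]))

    @property
    def position(self) -> tuple[float, float]:
        return self.position_at(self.traversed)


def _astar(network: RoadNetwork, origin: int, dest: int):
    """A* over the road graph; returns (node path, cost, expansions)."""
    tx, ty = network.node_xy(dest)

    def h(n: int) -> float:
        x, y = network.node_xy(n)
        return math.hypot(x - tx, y - ty)

    open_heap: list[tuple[float, int, int]] = [(h(origin), 0, origin)]
    g_score = {origin: 0.0}
    came: dict[int, int] = {}
    closed: set[int] = set()
    expansions = 0
    counter = 1
    while open_heap:
        _, _, node = heapq.heappop(open_heap)
        if node in closed:
            continue
        if node == dest:
            path = [node]
            while node in came:
                node = came[node]
                path.append(node)
            return path[::-1], g_score[dest], expansions
        closed.add(node)
        expansions += 1
        for nbr, w in network.adjacency[node]:
            if nbr in closed:
                continue
            tentative = g_score[node] + w
            if tentative < g_score.get(nbr, math.inf):
                g_score[nbr] = tentative
                came[nbr] = node
                heapq.heappush(open_heap, (tentative + h(nbr), counter, nbr))
                counter += 1
    raise RoutingError(f"no path from node {origin} to node {dest}")


def shortest_path(network: RoadNetwork, origin: int, dest: int) -> Route:
    """Minimal-length route between two network nodes.

    ``origin == dest`` yields a zero-length route.
    """
    if origin == dest:
        p = np.array([network.node_xy(origin)])
        return Route([origin], p, np.zeros(1))
    nodes, _, expansions = _astar(network, origin, dest)
    points = np.array([network.node_xy(n) for n in nodes], dtype=float)
    # arc length follows edge lengths (>= straight-line chords); positions
    # interpolate along the chord proportionally to distance covered
    seg = np.array(
        [network.graph.edges[u, v]["length"] for u, v in zip(nodes, nodes[1:])]
    )
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return Route(nodes, points, cum, expansions=expansions)


def advance(
    route: Route, speed_m_per_s: float, dt_s: float
) -> tuple[tuple[float, float], bool]:
    """Move along the route for one step; never overshoots the destination.

    Returns the new position and whether the destination has been reached.
    """
    if route.arrived:
        raise ValueError("route already complete")
    route.traversed = min(route.traversed + speed_m_per_s * dt_s,
                          route.total_length)
    return route.position, route.arrived


@dataclass
class PathCache:
    """Memoised shortest paths between node pairs (routes are symmetric in
    cost but cached per ordered pair to keep sensor-entry bookkeeping simple)."""

    network: RoadNetwork
    _store: dict[tuple[int, int], Route] = field(default_factory=dict)

    def route(self, origin: int, dest: int) -> Route:
        key = (origin, dest)
        tpl = self._store.get(key)
        if tpl is None:
            tpl = shortest_path(self.network, origin, dest)
            self._store[key] = tpl
        return tpl
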