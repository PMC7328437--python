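"""The spatial world: road network, function-tagged buildings, zones, sensors.

Coordinates are planar metres throughout (a projected CRS is assumed at the
I/O boundary; the simulator itself never reprojects).  Buildings and sensors
snap to their nearest road-network node and all travel happens on the
network.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from shapely.geometry import shape

from .activities import ACTIVITY_FUNCTION, BUILDING_FUNCTIONS

__all__ = [
    "RoadNetwork",
    "Building",
    "Zone",
    "Sensor",
    "Town",
    "load_town",
    "save_town",
    "generate_synthetic_town",
    "nearest_node",
    "TownValidationError",
]

DEFAULT_SENSOR_RADIUS_M = 20.0
#: Buildings/sensors may lie at most this far outside the road-node bounding box.
BBOX_MARGIN_M = 250.0
_LENGTH_TOL = 1e-6


class TownValidationError(ValueError):
    """Raised when a town description violates a structural invariant."""


@dataclass(frozen=True)
class Building:
    id: str
    x: float
    y: float
    function: str
    zone_id: str

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class Sensor:
    id: str
    x: float
    y: float
    radius_m: float = DEFAULT_SENSOR_RADIUS_M

    def __post_init__(self) -> None:
        if self.radius_m <= 0:
            raise TownValidationError(f"sensor {self.id}: detection radius must be > 0")

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class Zone:
    id: str
    building_ids: list[str] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)


class RoadNetwork:
    """Undirected street graph with metric node coordinates and edge lengths."""

    def __init__(self, graph: nx.Graph):
        self.graph = graph
        self.node_ids: list[int] = sorted(graph.nodes)
        self._index = {n: i for i, n in enumerate(self.node_ids)}
        self.coords = np.array(
            [[graph.nodes[n]["x"], graph.nodes[n]["y"]] for n in self.node_ids],
            dtype=float,
        ).reshape(-1, 2)
        # adjacency in plain dicts/lists for the router
        self.adjacency: dict[int, list[tuple[int, float]]] = {
            n: [] for n in self.node_ids
        }
        for u, v, data in graph.edges(data=True):
            w = float(data["length"])
            self.adjacency[u].append((v, w))
            self.adjacency[v].append((u, w))

    def __len__(self) -> int:
        return len(self.node_ids)

    def node_xy(self, node: int) -> tuple[float, float]:
        i = self._index[node]
        return (float(self.coords[i, 0]), float(self.coords[i, 1]))

    def validate(self) -> None:
        g = self.graph
        if g.number_of_nodes() == 0:
            raise TownValidationError("empty road network")
        if not nx.is_connected(g):
            sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
            raise TownValidationError(
                f"disconnected road network: component sizes {sizes}"
            )
        for u, v, data in g.edges(data=True):
            w = float(data["length"])
            eu = math.dist(self.node_xy(u), self.node_xy(v))
            if w <= 0:
                raise TownValidationError(f"edge ({u},{v}) has non-positive length")
            if w < eu - _LENGTH_TOL:
                raise TownValidationError(
                    f"edge ({u},{v}) length {w:.3f} m is shorter than the "
                    f"Euclidean distance {eu:.3f} m between its endpoints"
                )

    def nearest_node(self, point) -> int:
        """Node minimising Euclidean distance; ties go to the smallest id."""
        if len(self.node_ids) == 0:
            raise TownValidationError("empty road network")
        p = np.asarray(point, dtype=float)
        d2 = np.sum((self.coords - p) ** 2, axis=1)
        # node_ids is sorted, argmin returns the first (=smallest id) minimum
        return self.node_ids[int(np.argmin(d2))]

    def bbox(self) -> tuple[float, float, float, float]:
        return (
            float(self.coords[:, 0].min()),
            float(self.coords[:, 1].min()),
            float(self.coords[:, 0].max()),
            float(self.coords[:, 1].max()),
        )


class Town:
    """Immutable spatial world: network + buildings + zones + sensors.

    On construction every building and sensor is mapped to its nearest
    network node and all structural invariants are checked.
    """

    def __init__(
        self,
        network: RoadNetwork,
        buildings: list[Building],
        sensors: list[Sensor],
        required_functions: tuple[str, ...] | None = None,
    ):
        self.network = network
        self.buildings = list(buildings)
        self.sensors = list(sensors)
        self.building_by_id = {b.id: b for b in self.buildings}
        if len(self.building_by_id) != len(self.buildings):
            raise TownValidationError("duplicate building ids")

        network.validate()
        xmin, ymin, xmax, ymax = network.bbox()
        m = BBOX_MARGIN_M
        for b in self.buildings:
            if b.function not in BUILDING_FUNCTIONS:
                raise TownValidationError(
                    f"building {b.id}: unknown function {b.function!r}"
                )
            if not (xmin - m <= b.x <= xmax + m and ymin - m <= b.y <= ymax + m):
                raise TownValidationError(
                    f"building {b.id} lies outside the town bounding box"
                )

        self.building_node = {b.id: network.nearest_node(b.xy) for b in self.buildings}
        self.sensor_node = {s.id: network.nearest_node(s.xy) for s in self.sensors}

        self.zones: dict[str, Zone] = {}
        for b in self.buildings:
            self.zones.setdefault(b.zone_id, Zone(b.zone_id)).building_ids.append(b.id)

        self.buildings_by_function: dict[str, list[Building]] = {
            f: [] for f in BUILDING_FUNCTIONS
        }
        for b in self.buildings:
            self.buildings_by_function[b.function].append(b)

        # which functions must be present depends on the configured
        # activities, which are unknown at load time; the simulation engine
        # re-checks the functions its activities actually need
        missing = [f for f in required_functions or () if not self.buildings_by_function[f]]
        if missing:
            raise TownValidationError(
                f"town has no building for required function(s): {', '.join(missing)}"
            )

    def buildings_in_zone(self, zone_id: str, function: str | None = None):
        ids = self.zones[zone_id].building_ids
        out = [self.building_by_id[i] for i in ids]
        if function is not None:
            out = [b for b in out if b.function == function]
        return out

    def bbox(self) -> tuple[float, float, float, float]:
        return self.network.bbox()


def nearest_node(town: Town, point) -> int:
    """Network node nearest (Euclidean) to ``point``; ties to the smallest id."""
    return town.network.nearest_node(point)


# --------------------------------------------------------------------- I/O


def _read_network(network_dir: str | Path) -> RoadNetwork:
    network_dir = Path(network_dir)
    g = nx.Graph()
    with open(network_dir / "nodes.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            g.add_node(int(row["id"]), x=float(row["x"]), y=float(row["y"]))
    with open(network_dir / "edges.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            u, v = int(row["u"]), int(row["v"])
            if u not in g or v not in g:
                raise TownValidationError(f"edge ({u},{v}) references unknown node")
            length = row.get("length_m")
            if length in (None, ""):
                w = math.dist(
                    (g.nodes[u]["x"], g.nodes[u]["y"]),
                    (g.nodes[v]["x"], g.nodes[v]["y"]),
                )
            else:
                w = float(length)
            g.add_edge(u, v, length=w)
    return RoadNetwork(g)


def load_town(
    buildings_path: str | Path,
    network_path: str | Path,
    sensors_path: str | Path,
) -> Town:
    """Load and validate a town.

    Parameters
    ----------
    buildings_path : GeoJSON FeatureCollection of Point or Polygon features
        with ``id``, ``function`` and ``zone_id`` properties.  Polygons are
        reduced to the mean of their exterior-ring vertices.
    network_path : directory containing ``nodes.csv`` (id,x,y) and
        ``edges.csv`` (u,v,length_m; length optional, default Euclidean).
    sensors_path : CSV with columns id,x,y,radius_m.
    """
    with open(buildings_path) as fh:
        collection = json.load(fh)
    buildings = []
    for feat in collection["features"]:
        props = feat.get("properties", {})
        fid = str(props.get("id", ""))
        function = props.get("function")
        if function not in BUILDING_FUNCTIONS:
            raise TownValidationError(
                f"building feature {fid or '<missing id>'}: "
                f"missing or unknown function tag {function!r}"
            )
        geom = feat["geometry"]
        if geom["type"] == "Point":
            x, y = geom["coordinates"]
        elif geom["type"] == "Polygon":
            ring = geom["coordinates"][0]
            # drop the closing vertex if present, average the rest
            if len(ring) > 1 and ring[0] == ring[-1]:
                ring = ring[:-1]
            arr = np.asarray(ring, dtype=float)
            x, y = arr[:, 0].mean(), arr[:, 1].mean()
        else:
            # anything more exotic: shapely centroid
            c = shape(geom).centroid
            x, y = c.x, c.y
        buildings.append(
            Building(fid, float(x), float(y), function, str(props.get("zone_id", "")))
        )

    network = _read_network(network_path)

    sensors = []
    with open(sensors_path, newline="") as fh:
        for row in csv.DictReader(fh):
            radius = row.get("radius_m")
            sensors.append(
                Sensor(
                    str(row["id"]),
                    float(row["x"]),
                    float(row["y"]),
                    float(radius) if radius not in (None, "") else DEFAULT_SENSOR_RADIUS_M,
                )
            )
    return Town(network, buildings, sensors)


def save_town(town: Town, out_dir: str | Path) -> dict[str, Path]:
    """Write a town back to disk in the same formats ``load_town`` reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [b.x, b.y]},
            "properties": {"id": b.id, "function": b.function, "zone_id": b.zone_id},
        }
        for b in town.buildings
    ]
    paths = {
        "buildings": out_dir / "buildings.geojson",
        "nodes": out_dir / "nodes.csv",
        "edges": out_dir / "edges.csv",
        "sensors": out_dir / "sensors.csv",
    }
    with open(paths["buildings"], "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)

    net = town.network
    with open(paths["nodes"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "x", "y"])
        for n in net.node_ids:
            x, y = net.node_xy(n)
            w.writerow([n, repr(x), repr(y)])
    with open(paths["edges"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["u", "v", "length_m"])
        for u, v, data in sorted(net.graph.edges(data=True)):
            w.writerow([u, v, repr(float(data["length"]))])
    with open(paths["sensors"], "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "x", "y", "radius_m"])
        for s in town.sensors:
            w.writerow([s.id, repr(s.x), repr(s.y), repr(s.radius_m)])
    return paths


def load_town_dir(town_dir: str | Path) -> Town:
    """Convenience loader for a directory produced by :func:`save_town`."""
    town_dir = Path(town_dir)
    return load_town(town_dir / "buildings.geojson", town_dir, town_dir / "sensors.csv")


# ------------------------------------------------------- synthetic generator

DEFAULT_FUNCTION_MIX: dict[str, float] = {
    "residential": 0.50,
    "office": 0.15,
    "supermarket": 0.07,
    "leisure_shop": 0.07,
    "restaurant": 0.07,
    "pub": 0.07,
    "sports_facility": 0.07,
}

GRID_SPACING_M = 150.0


def generate_synthetic_town(
    n_blocks: int = 6,
    buildings_per_block: int = 12,
    function_mix: dict[str, float] | None = None,
    n_sensors: int = 8,
    seed: int = 0,
    spacing_m: float = GRID_SPACING_M,
    sensor_radius_m: float = DEFAULT_SENSOR_RADIUS_M,
) -> Town:
    """Generate a deterministic grid town.

    A ``(n_blocks+1) x (n_blocks+1)`` grid of street nodes with ``spacing_m``
    edges; each block is one statistical zone containing
    ``buildings_per_block`` buildings placed just off the block's perimeter
    streets with functions drawn from ``function_mix``; sensors sit on the
    most central nodes (emulating town-centre footfall sensors).
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    mix = dict(DEFAULT_FUNCTION_MIX if function_mix is None else function_mix)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("function_mix must sum to 1")
    required = sorted({"residential", "office", *ACTIVITY_FUNCTION.values()})
    missing = [f for f in required if mix.get(f, 0.0) <= 0.0]
    if missing:
        raise TownValidationError(
            "function_mix omits function(s) required by the default activity "
            f"configuration: {', '.join(missing)}"
        )

    rng = np.random.default_rng(seed)
    side = n_blocks + 1
    g = nx.Graph()
    for i in range(side):
        for j in range(side):
            g.add_node(i * side + j, x=j * spacing_m, y=i * spacing_m)
    for i in range(side):
        for j in range(side):
            n = i * side + j
            if j + 1 < side:
                g.add_edge(n, n + 1, length=spacing_m)
            if i + 1 < side:
                g.add_edge(n, n + side, length=spacing_m)

    functions = list(mix)
    base_probs = np.array([mix[f] for f in functions])
    centre_xy = np.array([n_blocks * spacing_m / 2.0] * 2)
    span = n_blocks * spacing_m
    buildings: list[Building] = []
    for bi in range(n_blocks):
        for bj in range(n_blocks):
            zone = f"z{bi}_{bj}"
            # commercial functions cluster in the town centre (where the
            # sensors sit); residential dominates the periphery
            block_xy = np.array([(bj + 0.5) * spacing_m, (bi + 0.5) * spacing_m])
            c = math.exp(-np.linalg.norm(block_xy - centre_xy) / (0.08 * span))
            probs = np.array(
                [
                    p * (1.0 - c + 0.15) if f == "residential" else p * (c + 0.02)
                    for f, p in zip(functions, base_probs)
                ]
            )
            probs /= probs.sum()
            draws = rng.choice(len(functions), size=buildings_per_block, p=probs)
            tags = [functions[k] for k in draws]
            # every zone hosts at least one residential building so that it
            # can appear in population tables
            if "residential" not in tags:
                tags[0] = "residential"
            for k, fn in enumerate(tags):
                # place along the block perimeter, inset a few metres
                t = rng.uniform(0.0, 4.0)
                edge, frac = int(t), t - int(t)
                x0, y0 = bj * spacing_m, bi * spacing_m
                inset = 8.0
                if edge == 0:  # south
                    x, y = x0 + frac * spacing_m, y0 + inset
                elif edge == 1:  # east
                    x, y = x0 + spacing_m - inset, y0 + frac * spacing_m
                elif edge == 2:  # north
                    x, y = x0 + (1 - frac) * spacing_m, y0 + spacing_m - inset
                else:  # west
                    x, y = x0 + inset, y0 + (1 - frac) * spacing_m
                buildings.append(
                    Building(f"b{bi}_{bj}_{k}", float(x), float(y), fn, zone)
                )

    # small towns may miss a function by chance; repurpose spare buildings
    # (never a zone's enforced first residential) to cover every required one
    from collections import Counter

    counts = Counter(b.function for b in buildings)
    for fn in (f for f in required if counts[f] == 0):
        spare = [
            i
            for i, b in enumerate(buildings)
            if counts[b.function] > 1 and not b.id.endswith("_0")
        ]
        if not spare:
            raise TownValidationError(
                f"too few buildings to provide required function {fn!r}"
            )
        i = spare[-1]
        counts[buildings[i].function] -= 1
        counts[fn] += 1
        b = buildings[i]
        buildings[i] = Building(b.id, b.x, b.y, fn, b.zone_id)

    centre = np.array([n_blocks * spacing_m / 2.0] * 2)
    net = RoadNetwork(g)
    d = np.linalg.norm(net.coords - centre, axis=1)
    order = np.lexsort((net.node_ids, d))  # by distance, ties by node id
    sensor_nodes = [net.node_ids[i] for i in order[: min(n_sensors, len(net))]]
    sensors = [
        Sensor(f"s{k}", *net.node_xy(n), sensor_radius_m)
        for k, n in enumerate(sensor_nodes)
    ]
    return Town(net, buildings, sensors, required_functions=tuple(required))
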