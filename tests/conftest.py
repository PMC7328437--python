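"""Shared fixtures: toy towns, toy parameter sets, small demo inputs."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from surf.environment import Building, RoadNetwork, Sensor, Town
from surf.params import ActivityParams, GlobalParams, ModelParams


def build_town(nodes, edges, buildings, sensors=(), required=()):
    """Hand-built town.

    ``nodes``: {id: (x, y)}; ``edges``: [(u, v)] or [(u, v, length)];
    ``buildings``: [(id, x, y, function, zone)]; ``sensors``:
    [(id, x, y, radius)].
    """
    g = nx.Graph()
    for nid, (x, y) in nodes.items():
        g.add_node(nid, x=float(x), y=float(y))
    for e in edges:
        u, v = e[0], e[1]
        length = (
            e[2]
            if len(e) > 2
            else float(np.hypot(nodes[u][0] - nodes[v][0], nodes[u][1] - nodes[v][1]))
        )
        g.add_edge(u, v, length=length)
    blds = [Building(b[0], float(b[1]), float(b[2]), b[3], b[4]) for b in buildings]
    sens = [Sensor(s[0], float(s[1]), float(s[2]), float(s[3])) for s in sensors]
    return Town(RoadNetwork(g), blds, sens, required_functions=tuple(required))


def make_params(table, *, step_minutes=5.0, sigma_rate=0.0, window_offset_min=0.0,
                daily_jitter_min=0.0, **g):
    """Toy parameter set with noise off by default.

    ``table``: {(group, activity): dict of ActivityParams kwargs}.
    """
    glob = GlobalParams(
        sigma_rate=sigma_rate,
        window_offset_min=window_offset_min,
        daily_jitter_min=daily_jitter_min,
        step_minutes=step_minutes,
        **g,
    )
    return ModelParams(glob, {k: ActivityParams(**v) for k, v in table.items()})


#: Minimal commuter day: home all night, office 08:15-16:45.
HOME_WORK_TABLE = {
    ("commuter", "at_home"): dict(
        grow_rate=0.0008, decay_rate=0.004, amplitude=1.0, baseline=0.5,
        window_start=20.5 * 60, window_end=8.75 * 60, min_duration_min=60.0,
    ),
    ("commuter", "work"): dict(
        grow_rate=0.0, decay_rate=0.004, amplitude=1.6,
        window_start=8.25 * 60, window_end=16.75 * 60, min_duration_min=60.0,
    ),
}


@pytest.fixture
def home_work_params():
    return make_params(HOME_WORK_TABLE)


@pytest.fixture
def line_town():
    """Home -- sensor node -- office on a straight 3-node street."""
    return build_town(
        nodes={0: (0, 0), 1: (400, 0), 2: (800, 0)},
        edges=[(0, 1), (1, 2)],
        buildings=[
            ("h", 5, 5, "residential", "z0"),
            ("w", 795, 5, "office", "z1"),
        ],
        sensors=[("s0", 400, 0, 20)],
    )


@pytest.fixture(scope="session")
def demo_small(tmp_path_factory):
    """Small but complete demo input set (town, tables, observed series)."""
    from surf.fixtures import FixtureSpec, make_demo_inputs

    out = tmp_path_factory.mktemp("demo_small")
    spec = FixtureSpec(
        seed=7, n_blocks=4, buildings_per_block=8, n_sensors=4,
        n_commuters=150, n_retired=150, obs_replicates=2, obs_days=6,
    )
    return make_demo_inputs(spec, out)
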