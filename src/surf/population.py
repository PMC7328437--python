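"""Agent population synthesis from census-style tables.

Commuters come from an origin-destination (OD) matrix of zone-to-zone
commuting counts: one agent per person-unit, with a home sampled uniformly
among the residential buildings of the home zone and a workplace sampled
uniformly among the offices of the work zone.  Retired agents come from
per-zone counts and have only a home anchor.

Per-agent heterogeneity makes agents' motivation dynamics differ:

* a log-normal multiplier per activity on the background grow rate,
* an independent log-normal multiplier per activity on the decay rate,
* a log-normal episode-duration factor per activity (scales the minimal
  duration up and the effective decay rate down by the same factor, so an
  agent's recurrence pattern is independent of how long its episodes last),
* a uniform offset (minutes) applied to all of the agent's time windows.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .activities import ACTIVITIES, activities_for
from .environment import Town
from .params import ModelParams

__all__ = ["ODMatrix", "AgentSpec", "load_od_matrix", "load_retired_counts",
           "synthesize_population", "save_population", "load_population"]


@dataclass
class ODMatrix:
    """Zone-to-zone commuter counts."""

    entries: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.entries.values())

    def __iter__(self):
        return iter(sorted(self.entries.items()))


@dataclass
class AgentSpec:
    """One simulated person: group, anchors and heterogeneity draws."""

    id: int
    group: str
    home_building: str
    work_building: str | None = None
    # per-activity heterogeneity, keyed by activity name
    rate_multiplier: dict[str, float] = field(default_factory=dict)
    decay_multiplier: dict[str, float] = field(default_factory=dict)
    duration_factor: dict[str, float] = field(default_factory=dict)
    window_offset_min: float = 0.0


def load_od_matrix(path: str | Path, town: Town) -> ODMatrix:
    """Read a ``home_zone,work_zone,count`` CSV; duplicate pairs are summed."""
    od = ODMatrix()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            home, work = str(row["home_zone"]), str(row["work_zone"])
            count = int(row["count"])
            if count < 0:
                raise ValueError(f"negative commuter count for ({home},{work})")
            for z in (home, work):
                if z not in town.zones:
                    raise ValueError(f"unknown zone id {z!r} in OD matrix")
            if count:
                key = (home, work)
                od.entries[key] = od.entries.get(key, 0) + count
    return od


def load_retired_counts(path: str | Path, town: Town) -> dict[str, int]:
    """Read a ``zone,count`` CSV of retired residents per zone."""
    counts: dict[str, int] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            zone, count = str(row["zone"]), int(row["count"])
            if zone not in town.zones:
                raise ValueError(f"unknown zone id {zone!r} in retired counts")
            if count < 0:
                raise ValueError(f"negative retired count for zone {zone}")
            counts[zone] = counts.get(zone, 0) + count
    return counts


def _draw_heterogeneity(
    agent: AgentSpec, group: str, params: ModelParams, rng: np.random.Generator
) -> None:
    g = params.globals
    for ai in activities_for(group):
        name = ACTIVITIES[ai]
        if (group, name) not in params.table:
            continue
        p = params.get(group, name)
        agent.rate_multiplier[name] = float(rng.lognormal(0.0, g.sigma_rate)) \
            if g.sigma_rate > 0 else 1.0
        agent.decay_multiplier[name] = float(rng.lognormal(0.0, g.sigma_rate)) \
            if g.sigma_rate > 0 else 1.0
        agent.duration_factor[name] = float(rng.lognormal(0.0, p.duration_sigma)) \
            if p.duration_sigma > 0 else 1.0
    agent.window_offset_min = (
        float(rng.uniform(-g.window_offset_min, g.window_offset_min))
        if g.window_offset_min > 0
        else 0.0
    )


def synthesize_population(
    town: Town,
    od: ODMatrix,
    retired_counts: dict[str, int],
    params: ModelParams,
    seed: int = 0,
    scale: float = 1.0,
) -> list[AgentSpec]:
    """Instantiate agents from the census-style tables.

    One commuter per OD unit and one retired agent per count unit
    (``scale`` < 1 thins every table binomially for desk-scale runs).
    Deterministic given ``seed``.
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must be in (0, 1]")
    rng = np.random.default_rng(seed)
    agents: list[AgentSpec] = []
    next_id = 0

    for (home_zone, work_zone), count in od:
        if scale < 1.0:
            count = int(rng.binomial(count, scale))
        if count == 0:
            continue
        homes = town.buildings_in_zone(home_zone, "residential")
        if not homes:
            raise ValueError(
                f"zone {home_zone} has commuter demand but no residential building"
            )
        offices = town.buildings_in_zone(work_zone, "office")
        if not offices:
            raise ValueError(
                f"zone {work_zone} is a work destination but has no office building"
            )
        for _ in range(count):
            a = AgentSpec(
                id=next_id,
                group="commuter",
                home_building=homes[int(rng.integers(len(homes)))].id,
                work_building=offices[int(rng.integers(len(offices)))].id,
            )
            _draw_heterogeneity(a, "commuter", params, rng)
            agents.append(a)
            next_id += 1

    for zone, count in sorted(retired_counts.items()):
        if scale < 1.0:
            count = int(rng.binomial(count, scale))
        if count == 0:
            continue
        homes = town.buildings_in_zone(zone, "residential")
        if not homes:
            raise ValueError(
                f"zone {zone} has retired residents but no residential building"
            )
        for _ in range(count):
            a = AgentSpec(
                id=next_id,
                group="retired",
                home_building=homes[int(rng.integers(len(homes)))].id,
            )
            _draw_heterogeneity(a, "retired", params, rng)
            agents.append(a)
            next_id += 1

    return agents


def _pop_frame(agents: list[AgentSpec]) -> pd.DataFrame:
    rows = []
    for a in agents:
        row: dict = {
            "id": a.id,
            "group": a.group,
            "home_building": a.home_building,
            "work_building": a.work_building or "",
            "window_offset_min": a.window_offset_min,
        }
        for name in ACTIVITIES:
            row[f"rate_mult_{name}"] = a.rate_multiplier.get(name, "")
            row[f"decay_mult_{name}"] = a.decay_multiplier.get(name, "")
            row[f"duration_factor_{name}"] = a.duration_factor.get(name, "")
        rows.append(row)
    return pd.DataFrame(rows)


def save_population(agents: list[AgentSpec], path: str | Path) -> None:
    _pop_frame(agents).to_csv(path, index=False)


def load_population(path: str | Path) -> list[AgentSpec]:
    df = pd.read_csv(path, keep_default_na=False)
    agents = []
    for _, row in df.iterrows():
        a = AgentSpec(
            id=int(row["id"]),
            group=str(row["group"]),
            home_building=str(row["home_building"]),
            work_building=str(row["work_building"]) or None,
            window_offset_min=float(row["window_offset_min"]),
        )
        for name in ACTIVITIES:
            for attr, col in (
                ("rate_multiplier", f"rate_mult_{name}"),
                ("decay_multiplier", f"decay_mult_{name}"),
                ("duration_factor", f"duration_factor_{name}"),
            ):
                v = row.get(col, "")
                if v != "":
                    getattr(a, attr)[name] = float(v)
        agents.append(a)
    return agents
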