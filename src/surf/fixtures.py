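"""Synthetic demo inputs for the complete pipeline.

Generates a grid town, census-style commuting and retired-population tables,
a parameter file, and a pseudo-observed footfall series.  The observed
series is a reference simulation of the configured groups plus an *injected
un-modelled component* -- by default a school-shaped pulse peaking at 15:00
-- plus Poisson noise.  The injection leaves a structured residual when the
observed series is compared against a simulation of the configured groups
only, which is exactly the signal used to decide which demographic group to
add to the model next.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .environment import Town, generate_synthetic_town, save_town
from .params import ModelParams, default_params, default_params_path, save_params
from .population import AgentSpec, load_od_matrix, load_retired_counts, \
    synthesize_population
from .sensors import FootfallTable
from .simulation import RunConfig, run_replicates

__all__ = ["FixtureSpec", "make_demo_inputs", "DemoInputs"]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study area and demand tables."""

    seed: int = 42
    n_blocks: int = 6
    buildings_per_block: int = 12
    n_sensors: int = 8
    n_commuters: int = 2000
    n_retired: int = 2000
    school_pulse_hour: int = 15
    school_pulse_scale: float = 0.3   # pulse peak relative to peak sim footfall
    school_pulse_width_h: float = 1.0
    obs_noise: bool = True
    obs_replicates: int = 3
    obs_days: int = 14

    def __post_init__(self) -> None:
        if self.n_commuters < 0 or self.n_retired < 0:
            raise ValueError("group sizes must be >= 0")
        if self.school_pulse_scale < 0:
            raise ValueError("injected component must be >= 0")


@dataclass
class DemoInputs:
    town_dir: Path
    od_path: Path
    retired_path: Path
    params_path: Path
    obs_path: Path | None
    town: Town
    agents: list[AgentSpec]
    params: ModelParams


def _demand_tables(town: Town, spec: FixtureSpec, rng: np.random.Generator):
    """Commuting OD rows and retired counts over the town's zones.

    Workplaces are weighted towards the centre of the town (offices cluster
    there in the real study area); homes are spread uniformly.
    """
    res_zones = sorted(
        z for z, zone in town.zones.items()
        if town.buildings_in_zone(z, "residential")
    )
    office_zones = sorted(
        z for z, zone in town.zones.items() if town.buildings_in_zone(z, "office")
    )
    xmin, ymin, xmax, ymax = town.bbox()
    centre = np.array([(xmin + xmax) / 2.0, (ymin + ymax) / 2.0])
    span = max(xmax - xmin, 1.0)

    def zone_centroid(z):
        blds = town.buildings_in_zone(z)
        return np.array([[b.x, b.y] for b in blds]).mean(axis=0)

    w = np.array(
        [np.exp(-np.linalg.norm(zone_centroid(z) - centre) / (0.35 * span))
         for z in office_zones]
    )
    w /= w.sum()

    homes = rng.integers(len(res_zones), size=spec.n_commuters)
    works = rng.choice(len(office_zones), size=spec.n_commuters, p=w)
    od: dict[tuple[str, str], int] = {}
    for h, k in zip(homes, works):
        key = (res_zones[h], office_zones[k])
        od[key] = od.get(key, 0) + 1

    retired = np.bincount(
        rng.integers(len(res_zones), size=spec.n_retired), minlength=len(res_zones)
    )
    retired_counts = {
        res_zones[i]: int(c) for i, c in enumerate(retired) if c > 0
    }
    return od, retired_counts


def make_demo_inputs(
    spec: FixtureSpec | None = None,
    out_dir: str | Path = "demo",
    params: ModelParams | None = None,
    write_obs: bool = True,
) -> DemoInputs:
    """Write a complete runnable input set; deterministic given the seed."""
    spec = spec or FixtureSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    town = generate_synthetic_town(
        n_blocks=spec.n_blocks,
        buildings_per_block=spec.buildings_per_block,
        n_sensors=spec.n_sensors,
        seed=spec.seed,
    )
    town_dir = out_dir / "town"
    save_town(town, town_dir)

    od, retired_counts = _demand_tables(town, spec, rng)
    od_path = out_dir / "od.csv"
    with open(od_path, "w") as fh:
        fh.write("home_zone,work_zone,count\n")
        for (h, w), c in sorted(od.items()):
            fh.write(f"{h},{w},{c}\n")
    retired_path = out_dir / "retired.csv"
    with open(retired_path, "w") as fh:
        fh.write("zone,count\n")
        for z, c in sorted(retired_counts.items()):
            fh.write(f"{z},{c}\n")

    params_path = out_dir / "params.toml"
    if params is None:
        shutil.copyfile(default_params_path(), params_path)
        params = default_params()
    else:
        save_params(params, params_path)
    agents = synthesize_population(
        town,
        load_od_matrix(od_path, town),
        load_retired_counts(retired_path, town),
        params,
        seed=spec.seed,
    )

    obs_path: Path | None = None
    if write_obs:
        obs_path = out_dir / "obs.csv"
        config = RunConfig(
            n_days=spec.obs_days, n_replicates=spec.obs_replicates, seed=spec.seed
        )
        ref = run_replicates(town, agents, params, config)
        mean = ref.footfall.counts
        hours = np.arange(24)
        shape = np.exp(
            -0.5 * ((hours - spec.school_pulse_hour) / spec.school_pulse_width_h) ** 2
        )
        peak = mean.max(axis=1, keepdims=True) if mean.size else mean
        expected = mean + spec.school_pulse_scale * peak * shape[None, :]
        if spec.obs_noise:
            counts = rng.poisson(expected)
        else:
            counts = np.round(expected).astype(int)
        FootfallTable(
            counts=counts, sensor_ids=ref.footfall.sensor_ids
        ).save(obs_path)

    return DemoInputs(
        town_dir=town_dir,
        od_path=od_path,
        retired_path=retired_path,
        params_path=params_path,
        obs_path=obs_path,
        town=town,
        agents=agents,
        params=params,
    )
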