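"""Full simulation runs: populations over towns, replicates, aggregation.

The engine vectorises the activity-engine semantics over all agents with
numpy (agents do not interact, so synchronous updates are exact) and treats
travel explicitly: a switching agent commits to the shortest path to its
destination, moves at constant walking speed, and starts the destination
activity on arrival.  Sensor crossings are precomputed geometrically per
cached route, so a step that jumps across a small detection disc is still
counted.

Only the final simulated day is reported: footfall per sensor-hour and the
per-agent per-step activity log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activities import ACTIVITIES, ACTIVITY_FUNCTION, AT_HOME, TRAVEL, WORK, GROUPS
from .allocation import AllocationError, AllocationPolicy
from .environment import Town
from .mobility import PathCache
from .params import MINUTES_PER_DAY, ModelParams
from .population import AgentSpec
from .sensors import FootfallTable, polyline_disc_entries

__all__ = ["RunConfig", "RunResult", "AggregateResult", "run_simulation",
           "run_replicates", "bootstrap_ci", "SimulationEngine"]

K = len(ACTIVITIES)


@dataclass(frozen=True)
class RunConfig:
    """How a simulation is executed and reported."""

    n_days: int = 14
    n_replicates: int = 50
    warmup_days: int = 2
    seed: int = 0
    ci_level: float = 0.99
    n_bootstrap: int = 1000

    def __post_init__(self) -> None:
        if self.n_days <= self.warmup_days:
            raise ValueError("n_days must exceed warmup_days")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class RunResult:
    """One replicate: final-day footfall and activity log."""

    footfall: FootfallTable
    log: np.ndarray           # (n_agents, steps_per_day) int8; TRAVEL == -1
    groups: np.ndarray        # (n_agents,) group index into GROUPS
    step_minutes: float
    replicate_seed: int


@dataclass
class AggregateResult:
    """Replicate-aggregated result: mean footfall with bootstrap CIs plus
    the per-replicate activity logs."""

    footfall: FootfallTable
    logs: list[np.ndarray]
    groups: np.ndarray
    step_minutes: float
    config: RunConfig


class SimulationEngine:
    """Compiled simulation state for one (town, population, params) triple."""

    def __init__(
        self,
        town: Town,
        agents: list[AgentSpec],
        params: ModelParams,
        policy: AllocationPolicy | None = None,
    ):
        self.town = town
        self.agents = agents
        self.params = params
        g = params.globals
        self.policy = policy or AllocationPolicy(g.initial_radius_m, g.max_doublings)
        self.step_min = g.step_minutes
        self.steps_per_day = int(round(MINUTES_PER_DAY / self.step_min))
        self.speed = g.walking_speed_mps
        self.step_metres = self.speed * self.step_min * 60.0

        n = len(agents)
        self.n = n
        self.group_idx = np.array(
            [GROUPS.index(a.group) for a in agents], dtype=np.int64
        )
        self.applicable = np.zeros((n, K), dtype=bool)
        self.grow = np.zeros((n, K))
        self.decay = np.zeros((n, K))
        self.min_dur = np.ones((n, K))
        self.amp = np.zeros((n, K))
        self.base = np.zeros((n, K))
        self.ws = np.zeros((n, K))
        self.wlen = np.zeros((n, K))
        bld_ids = [b.id for b in town.buildings]
        bld_index = {bid: i for i, bid in enumerate(bld_ids)}
        self.bld_node = np.array(
            [town.building_node[bid] for bid in bld_ids], dtype=np.int64
        ) if bld_ids else np.zeros(0, dtype=np.int64)
        self.home_bld = np.zeros(n, dtype=np.int64)
        self.work_bld = np.full(n, -1, dtype=np.int64)
        for i, a in enumerate(agents):
            self.home_bld[i] = bld_index[a.home_building]
            if a.group == "commuter":
                if a.work_building is None:
                    raise ValueError(f"commuter agent {a.id} has no work building")
                self.work_bld[i] = bld_index[a.work_building]
            for ai, name in enumerate(ACTIVITIES):
                key = (a.group, name)
                if key not in params.table:
                    continue
                p = params.table[key]
                L = a.duration_factor.get(name, 1.0)
                self.applicable[i, ai] = True
                self.grow[i, ai] = (
                    p.grow_rate * a.rate_multiplier.get(name, 1.0) * self.step_min
                )
                self.decay[i, ai] = (
                    p.decay_rate * a.decay_multiplier.get(name, 1.0) / L * self.step_min
                )
                self.min_dur[i, ai] = max(
                    1, round(p.min_duration_min * L / self.step_min)
                )
                self.amp[i, ai] = p.amplitude
                self.base[i, ai] = p.baseline
                self.ws[i, ai] = (p.window_start + a.window_offset_min) % MINUTES_PER_DAY
                self.wlen[i, ai] = p.window_length

        self._garr = np.where(self.applicable, self.grow, 0.0)
        self._inf_mask = np.where(self.applicable, 0.0, -np.inf)
        self.jitter_scale = g.daily_jitter_min

        # allocation tables per building function
        self._alloc: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        needed = {
            ACTIVITY_FUNCTION[ACTIVITIES[ai]]
            for ai in range(K)
            if ACTIVITIES[ai] in ACTIVITY_FUNCTION and self.applicable[:, ai].any()
        }
        for fn in needed:
            blds = town.buildings_by_function[fn]
            if not blds:
                raise AllocationError(
                    f"configured activities require a {fn!r} building, "
                    "but the town has none"
                )
            coords = np.array([[b.x, b.y] for b in blds])
            idx = np.array([bld_index[b.id] for b in blds], dtype=np.int64)
            self._alloc[fn] = (coords, idx)

        self.paths = PathCache(town.network)
        self._route_entries: dict[tuple[int, int], list[tuple[int, float]]] = {}
        self._sensor_centres = np.array([s.xy for s in town.sensors]).reshape(-1, 2)
        self._sensor_radii = np.array([s.radius_m for s in town.sensors])
        self._node_xy = {nid: town.network.node_xy(nid) for nid in
                         town.network.node_ids}

    # ------------------------------------------------------------ internals

    def _entries_for(self, o: int, d: int, route) -> list[tuple[int, float]]:
        key = (o, d)
        out = self._route_entries.get(key)
        if out is None:
            out = []
            for si in range(len(self.town.sensors)):
                for arc in polyline_disc_entries(
                    route.points, self._sensor_centres[si], self._sensor_radii[si]
                ):
                    out.append((si, arc))
            self._route_entries[key] = out
        return out

    def _allocate(self, activity: int, node: int, rng: np.random.Generator) -> int:
        """Building index for a flexible activity near a node (radius doubling)."""
        fn = ACTIVITY_FUNCTION[ACTIVITIES[activity]]
        coords, idx = self._alloc[fn]
        xy = np.asarray(self._node_xy[node])
        d2 = np.sum((coords - xy) ** 2, axis=1)
        r = self.policy.initial_radius_m
        for _ in range(self.policy.max_doublings + 1):
            cand = np.flatnonzero(d2 <= r * r)
            if cand.size:
                return int(idx[cand[int(rng.integers(cand.size))]])
            r *= 2.0
        raise AllocationError(
            f"no {fn!r} building within "
            f"{self.policy.initial_radius_m * 2 ** self.policy.max_doublings:.0f} m"
        )

    # ------------------------------------------------------------------ run

    def run(self, replicate_seed: int) -> RunResult:
        """Execute one replicate; deterministic given ``replicate_seed``."""
        rng = np.random.default_rng(replicate_seed)
        n, spd = self.n, self.steps_per_day
        cfg_days = self._n_days
        n_steps = cfg_days * spd
        final_start_min = (cfg_days - 1) * MINUTES_PER_DAY

        B = np.zeros((n, K))
        if n:
            drain = self.decay * self.min_dur
            u = rng.uniform(0.0, 1.0, size=(n, K))
            B = np.where(self.applicable, u * drain, 0.0)
            B[:, AT_HOME] = 0.0
        current = np.full(n, AT_HOME, dtype=np.int64)
        elapsed = np.full(n, 10 ** 6, dtype=np.int64)
        cur_bld = self.home_bld.copy()
        node = self.bld_node[self.home_bld] if n else np.zeros(0, dtype=np.int64)
        travelling = np.zeros(n, dtype=bool)
        r_total = np.zeros(n)
        r_done = np.zeros(n)
        dest_act = np.zeros(n, dtype=np.int64)
        dest_bld = np.zeros(n, dtype=np.int64)
        dest_node = np.zeros(n, dtype=np.int64)

        jitter = np.zeros((n, K))
        events: list[tuple[float, int]] = []
        log = np.zeros((n, spd), dtype=np.int8)
        rows = np.arange(n)

        for t in range(n_steps):
            step_of_day = t % spd
            tod = step_of_day * self.step_min
            final_day = t // spd == cfg_days - 1
            if step_of_day == 0 and self.jitter_scale > 0 and n:
                jitter = rng.uniform(
                    -self.jitter_scale, self.jitter_scale, size=(n, K)
                )

            # 1. advance travellers; arrivals start their destination activity
            if travelling.any():
                trav = np.flatnonzero(travelling)
                r_done[trav] += self.step_metres
                arrived = trav[r_done[trav] >= r_total[trav] - 1e-9]
                if arrived.size:
                    current[arrived] = dest_act[arrived]
                    cur_bld[arrived] = dest_bld[arrived]
                    node[arrived] = dest_node[arrived]
                    elapsed[arrived] = 0
                    travelling[arrived] = False

            # 2. background dynamics
            if n:
                B += self._garr
                perf = np.flatnonzero(~travelling)
                pc = current[perf]
                B[perf, pc] -= self._garr[perf, pc]
                B[perf, pc] = np.maximum(0.0, B[perf, pc] - self.decay[perf, pc])
                elapsed[perf] += 1

            # 3. final-day logging (the activity performed during this step)
            if final_day and n:
                log[:, step_of_day] = np.where(travelling, TRAVEL, current)

            # 4. decisions
            if n:
                free = (~travelling) & (elapsed >= self.min_dur[rows, current])
                idx = np.flatnonzero(free)
                if idx.size:
                    rel = (tod - (self.ws[idx] + jitter[idx])) % MINUTES_PER_DAY
                    tvec = np.where(
                        rel < self.wlen[idx], self.amp[idx], self.base[idx]
                    )
                    totals = B[idx] + tvec + self._inf_mask[idx]
                    best = np.argmax(totals, axis=1)
                    ar = np.arange(idx.size)
                    switch = totals[ar, best] > totals[ar, current[idx]]
                    for i, a in zip(idx[switch], best[switch]):
                        a = int(a)
                        if a == AT_HOME:
                            b = int(self.home_bld[i])
                        elif a == WORK:
                            b = int(self.work_bld[i])
                        else:
                            b = self._allocate(a, int(node[i]), rng)
                        dnode = int(self.bld_node[b])
                        if dnode == node[i]:
                            current[i] = a
                            cur_bld[i] = b
                            elapsed[i] = 0
                            continue
                        route = self.paths.route(int(node[i]), dnode)
                        travelling[i] = True
                        r_total[i] = route.total_length
                        r_done[i] = 0.0
                        dest_act[i] = a
                        dest_bld[i] = b
                        dest_node[i] = dnode
                        depart_min = (t + 1) * self.step_min
                        for si, arc in self._entries_for(int(node[i]), dnode, route):
                            ev = depart_min + arc / (self.speed * 60.0)
                            if final_start_min <= ev < final_start_min + MINUTES_PER_DAY:
                                events.append((ev, si))

        counts = np.zeros((len(self.town.sensors), 24), dtype=int)
        for ev, si in events:
            counts[si, int((ev - final_start_min) // 60.0)] += 1
        table = FootfallTable(
            counts=counts, sensor_ids=[s.id for s in self.town.sensors]
        )
        return RunResult(
            footfall=table,
            log=log,
            groups=self.group_idx.copy(),
            step_minutes=self.step_min,
            replicate_seed=replicate_seed,
        )

    _n_days: int = 14

    def configure(self, config: RunConfig) -> "SimulationEngine":
        self._n_days = config.n_days
        return self


def run_simulation(
    town: Town,
    agents: list[AgentSpec],
    params: ModelParams,
    config: RunConfig | None = None,
    replicate_seed: int = 0,
) -> RunResult:
    """Run one replicate and report the final simulated day."""
    config = config or RunConfig()
    return SimulationEngine(town, agents, params).configure(config).run(replicate_seed)


def replicate_seed(master_seed: int, replicate: int) -> int:
    """Derive an independent replicate seed from the master seed."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(replicate,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def bootstrap_ci(
    stack: np.ndarray, level: float, seed: int, n_bootstrap: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile bootstrap CI of the replicate mean, per sensor-hour cell.

    The resampling plan depends only on ``seed`` and the replicate count, so
    intervals at nested levels computed from the same seed are themselves
    nested.
    """
    rng = np.random.default_rng(seed)
    r = stack.shape[0]
    picks = rng.integers(0, r, size=(n_bootstrap, r))
    boot = stack[picks].mean(axis=1)  # (n_bootstrap, S, 24)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(boot, alpha, axis=0)
    hi = np.quantile(boot, 1.0 - alpha, axis=0)
    return lo, hi


def run_replicates(
    town: Town,
    agents: list[AgentSpec],
    params: ModelParams,
    config: RunConfig | None = None,
    progress: bool = False,
) -> AggregateResult:
    """Run independent replicates and aggregate footfall (mean + bootstrap CI)."""
    config = config or RunConfig()
    if config.n_replicates < 1:
        raise ValueError("need at least one replicate")
    engine = SimulationEngine(town, agents, params).configure(config)
    stacks = []
    logs = []
    groups = None
    for r in range(config.n_replicates):
        res = engine.run(replicate_seed(config.seed, r))
        stacks.append(res.footfall.counts)
        logs.append(res.log)
        groups = res.groups
        if progress:
            print(f"replicate {r + 1}/{config.n_replicates} done")
    stack = np.array(stacks, dtype=float)
    mean = stack.mean(axis=0)
    if config.n_replicates >= 2:
        lo, hi = bootstrap_ci(
            stack, config.ci_level, replicate_seed(config.seed, 10 ** 6),
            config.n_bootstrap,
        )
    else:
        lo = hi = mean
    table = FootfallTable(
        counts=mean,
        sensor_ids=[s.id for s in town.sensors],
        replicates=stack,
        ci_lo=lo,
        ci_hi=hi,
        ci_level=config.ci_level,
    )
    return AggregateResult(
        footfall=table,
        logs=logs,
        groups=groups if groups is not None else np.zeros(0, dtype=np.int64),
        step_minutes=params.globals.step_minutes,
        config=config,
    )
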