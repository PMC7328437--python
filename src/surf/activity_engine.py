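"""Per-activity motivation intensities and the activity-selection rule.

Each applicable activity has a *background* intensity ``B`` that accumulates
linearly while the activity is not performed and drains (faster) while it is,
and a *time* intensity equal to an ``amplitude`` inside the activity's daily
time window and a ``baseline`` (normally zero) outside it.  The agent
performs the activity with the highest total intensity ``B + time``; a
minimal duration on the current activity prevents rapid switching, and exact
ties keep the current activity (ties among challengers resolve in canonical
activity order).

The functions here are scalar (one agent); :mod:`surf.simulation` contains a
vectorised implementation of identical semantics for whole populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activities import ACTIVITIES, AT_HOME, activities_for
from .params import MINUTES_PER_DAY, ActivityParams, ModelParams
from .population import AgentSpec

__all__ = [
    "AgentRates",
    "AgentState",
    "compile_agent_rates",
    "time_intensity",
    "update_background",
    "total_intensity",
    "choose_activity",
    "simulate_single_agent",
]

K = len(ACTIVITIES)


def time_intensity(
    p: ActivityParams, time_of_day_min: float, shift_min: float = 0.0
) -> float:
    """Time intensity of one activity at a time of day.

    ``shift_min`` shifts the window (agent offset plus daily jitter); the
    shifted window wraps at midnight.  Returns ``amplitude`` inside the
    window and ``baseline`` (0 unless configured otherwise) outside.
    """
    t = time_of_day_min % MINUTES_PER_DAY
    if not 0.0 <= time_of_day_min < MINUTES_PER_DAY:
        raise ValueError("time_of_day must lie in [0, 1440) minutes")
    start = (p.window_start + shift_min) % MINUTES_PER_DAY
    inside = (t - start) % MINUTES_PER_DAY < p.window_length
    return p.amplitude if inside else p.baseline


@dataclass
class AgentRates:
    """Per-agent effective parameters in step units (heterogeneity applied).

    The per-agent duration factor ``L`` multiplies the minimal duration and
    divides the decay rate, so the background drained per episode -- and with
    it the activity's recurrence interval -- is independent of ``L``.
    """

    applicable: np.ndarray   # (K,) bool
    grow: np.ndarray         # (K,) per step
    decay: np.ndarray        # (K,) per step
    min_duration: np.ndarray  # (K,) steps
    amplitude: np.ndarray    # (K,)
    baseline: np.ndarray     # (K,)
    window_start: np.ndarray  # (K,) minutes, agent offset included
    window_length: np.ndarray  # (K,) minutes
    step_minutes: float

    @property
    def episode_drain(self) -> np.ndarray:
        """Background drained by one minimal-length episode."""
        return self.decay * self.min_duration


def compile_agent_rates(
    params: ModelParams, group: str, agent: AgentSpec | None = None
) -> AgentRates:
    """Resolve the parameter table plus one agent's draws into step-unit arrays."""
    step = params.globals.step_minutes
    applicable = np.zeros(K, dtype=bool)
    grow = np.zeros(K)
    decay = np.full(K, 1.0)
    min_dur = np.ones(K)
    amp = np.zeros(K)
    base = np.zeros(K)
    ws = np.zeros(K)
    wlen = np.zeros(K)
    offset = agent.window_offset_min if agent is not None else 0.0
    for ai in activities_for(group):
        name = ACTIVITIES[ai]
        if (group, name) not in params.table:
            continue
        p = params.get(group, name)
        mg = agent.rate_multiplier.get(name, 1.0) if agent else 1.0
        md = agent.decay_multiplier.get(name, 1.0) if agent else 1.0
        L = agent.duration_factor.get(name, 1.0) if agent else 1.0
        applicable[ai] = True
        grow[ai] = p.grow_rate * mg * step
        decay[ai] = p.decay_rate * md / L * step
        min_dur[ai] = max(1, round(p.min_duration_min * L / step))
        amp[ai] = p.amplitude
        base[ai] = p.baseline
        ws[ai] = (p.window_start + offset) % MINUTES_PER_DAY
        wlen[ai] = p.window_length
    return AgentRates(applicable, grow, decay, min_dur, amp, base, ws, wlen, step)


@dataclass
class AgentState:
    """Dynamic state of one agent."""

    activity: int = AT_HOME
    elapsed: int = 10 ** 6        # steps spent in the current activity
    background: np.ndarray = field(default_factory=lambda: np.zeros(K))
    travelling: bool = False
    node: int | None = None       # current network node when not travelling


def init_background(
    rates: AgentRates, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Stationary initial background: uniform on [0, per-episode drain].

    The background of a recurrent activity follows a sawtooth between ~0 and
    the amount one episode drains; drawing initial values uniformly on that
    range spreads agents' recurrence phases so that day-one statistics are
    already representative.
    """
    b = np.zeros(K)
    if rng is not None:
        u = rng.uniform(0.0, 1.0, K)
        b = np.where(rates.applicable, u * rates.episode_drain, 0.0)
    b[AT_HOME] = 0.0
    return b


def update_background(
    state: AgentState, rates: AgentRates, dt_steps: int = 1
) -> np.ndarray:
    """Advance background intensities by ``dt_steps``.

    The performed activity drains (clipped at zero); every other applicable
    activity grows.  While travelling no activity counts as performed, so all
    grow.  Returns the new background vector (state is updated in place).
    """
    b = state.background
    for _ in range(dt_steps):
        growth = np.where(rates.applicable, rates.grow, 0.0)
        if not state.travelling:
            growth[state.activity] = 0.0
        b = b + growth
        if not state.travelling:
            a = state.activity
            b[a] = max(0.0, b[a] - rates.decay[a])
    state.background = b
    return b


def _time_vector(
    rates: AgentRates, time_of_day_min: float, jitter: np.ndarray | None = None
) -> np.ndarray:
    start = rates.window_start if jitter is None else rates.window_start + jitter
    rel = (time_of_day_min - start) % MINUTES_PER_DAY
    inside = rel < rates.window_length
    return np.where(inside, rates.amplitude, rates.baseline)


def total_intensity(
    state: AgentState,
    rates: AgentRates,
    time_of_day_min: float,
    jitter: np.ndarray | None = None,
) -> dict[str, float]:
    """Total (background + time) intensity per applicable activity."""
    if not rates.applicable.any():
        raise ValueError("agent group has no configured activities")
    tot = state.background + _time_vector(rates, time_of_day_min, jitter)
    return {
        ACTIVITIES[i]: float(tot[i]) for i in range(K) if rates.applicable[i]
    }


def choose_activity(
    state: AgentState, totals: dict[str, float] | np.ndarray, rates: AgentRates
) -> int:
    """The activity-selection rule.

    Keeps the current activity while its minimal duration has not elapsed;
    otherwise switches to the highest-total activity.  An exact tie with the
    current activity keeps it; ties among other activities resolve in
    canonical activity order.
    """
    if isinstance(totals, dict):
        if not totals:
            raise ValueError("empty totals: misconfigured group")
        arr = np.full(K, -np.inf)
        for name, v in totals.items():
            arr[ACTIVITIES.index(name)] = v
    else:
        arr = np.where(rates.applicable, totals, -np.inf)
        if not np.isfinite(arr).any():
            raise ValueError("empty totals: misconfigured group")
    cur = state.activity
    if state.elapsed < rates.min_duration[cur]:
        return cur
    best = int(np.argmax(arr))  # first maximum = canonical order
    return best if arr[best] > arr[cur] else cur


def simulate_single_agent(
    params: ModelParams,
    group: str = "commuter",
    agent: AgentSpec | None = None,
    n_days: int = 14,
    seed: int | None = None,
    stationary_init: bool = False,
) -> np.ndarray:
    """Pure behavioural trace of one agent with travel disabled (teleporting).

    Returns the per-step activity index over ``n_days``.  With heterogeneity
    and jitter switched off (``params.noise_free()``) and no seed the trace
    is fully deterministic.
    """
    rates = compile_agent_rates(params, group, agent)
    rng = np.random.default_rng(seed) if seed is not None else None
    state = AgentState(
        background=init_background(rates, rng if stationary_init else None)
    )
    step = params.globals.step_minutes
    steps_per_day = int(round(MINUTES_PER_DAY / step))
    jitter_scale = params.globals.daily_jitter_min
    jitter = np.zeros(K)
    log = np.empty(n_days * steps_per_day, dtype=np.int8)
    for t in range(len(log)):
        tod = (t % steps_per_day) * step
        if t % steps_per_day == 0 and jitter_scale > 0 and rng is not None:
            jitter = rng.uniform(-jitter_scale, jitter_scale, size=K)
        update_background(state, rates)
        state.elapsed += 1
        log[t] = state.activity
        if state.elapsed >= rates.min_duration[state.activity]:
            totals = state.background + _time_vector(rates, tod, jitter)
            new = choose_activity(state, np.asarray(totals), rates)
            if new != state.activity:
                state.activity = new
                state.elapsed = 0
    return log
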