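"""Model parameters: intensity dynamics per (group, activity) plus globals.

Rates are expressed per *minute* so that configurations are independent of the
simulation step length.  The engine multiplies by ``step_minutes``.

The intensity model: each activity carries a *background* intensity that grows
linearly (``grow_rate``) while the activity is not performed and drains
linearly (``decay_rate``) while it is, and a *time* intensity that equals
``amplitude`` inside the activity's daily time window and ``baseline``
(usually 0) outside it.  An agent performs the activity with the highest
total (background + time) intensity, subject to a minimal duration on the
current activity.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

from .activities import ACTIVITIES, ACTIVITY_GROUPS, GROUPS

MINUTES_PER_DAY = 1440.0


def parse_clock(value: str | float | int) -> float:
    """Parse a time of day ("HH:MM" or minutes) into minutes from midnight."""
    if isinstance(value, str):
        hh, mm = value.split(":")
        minutes = int(hh) * 60.0 + float(mm)
    else:
        minutes = float(value)
    if not 0.0 <= minutes < MINUTES_PER_DAY:
        raise ValueError(f"time of day {value!r} outside [00:00, 24:00)")
    return minutes


def format_clock(minutes: float) -> str:
    return f"{int(minutes) // 60:02d}:{int(minutes) % 60:02d}"


@dataclass(frozen=True)
class ActivityParams:
    """Intensity parameters for one (group, activity) pair.

    Parameters
    ----------
    grow_rate : float
        Background growth per minute while the activity is not performed.
    decay_rate : float
        Background drain per minute while performing; must exceed grow_rate
        so any accumulated motivation can always be worked off.
    amplitude : float
        Time intensity inside the daily window.
    baseline : float
        Time intensity outside the window (0 for all flexible activities).
    window_start, window_end : float
        Window edges in minutes from midnight; the window may wrap midnight.
    min_duration_min : float
        Median minimal episode duration in minutes.
    duration_sigma : float
        Log-normal sigma of the per-agent episode-duration factor
        (0 disables duration heterogeneity for this activity).
    """

    grow_rate: float
    decay_rate: float
    amplitude: float
    window_start: float
    window_end: float
    min_duration_min: float
    baseline: float = 0.0
    duration_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not (self.decay_rate > self.grow_rate >= 0.0):
            raise ValueError(
                f"require decay_rate > grow_rate >= 0, got "
                f"decay={self.decay_rate}, grow={self.grow_rate}"
            )
        if self.amplitude < 0.0 or self.baseline < 0.0:
            raise ValueError("amplitude and baseline must be >= 0")
        if self.min_duration_min < 1.0:
            raise ValueError("min_duration_min must be >= 1 minute")
        if self.duration_sigma < 0.0:
            raise ValueError("duration_sigma must be >= 0")
        for edge in (self.window_start, self.window_end):
            if not 0.0 <= edge < MINUTES_PER_DAY:
                raise ValueError("window edges must lie in [00:00, 24:00)")

    @property
    def window_length(self) -> float:
        return (self.window_end - self.window_start) % MINUTES_PER_DAY


@dataclass(frozen=True)
class GlobalParams:
    """Model-wide knobs (heterogeneity scales, movement, allocation)."""

    sigma_rate: float = 0.2          # lognormal sigma of per-agent rate multipliers
    window_offset_min: float = 30.0  # per-agent uniform window shift (+-)
    daily_jitter_min: float = 10.0   # per-agent per-day uniform window jitter (+-)
    walking_speed_mps: float = 1.4
    step_minutes: float = 5.0
    initial_radius_m: float = 500.0
    max_doublings: int = 6

    def __post_init__(self) -> None:
        if self.step_minutes <= 0 or 60.0 % self.step_minutes:
            raise ValueError("step_minutes must divide 60")
        if self.walking_speed_mps <= 0:
            raise ValueError("walking_speed_mps must be > 0")


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter set: globals plus per-(group, activity) intensities."""

    globals: GlobalParams = field(default_factory=GlobalParams)
    table: dict[tuple[str, str], ActivityParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for group, activity in self.table:
            if group not in GROUPS:
                raise ValueError(f"unknown group {group!r}")
            if activity not in ACTIVITIES:
                raise ValueError(f"unknown activity {activity!r}")
            if group not in ACTIVITY_GROUPS[activity]:
                raise ValueError(f"activity {activity!r} not applicable to {group!r}")

    def get(self, group: str, activity: str) -> ActivityParams:
        return self.table[(group, activity)]

    def activities_for(self, group: str) -> list[str]:
        return [a for (g, a) in self.table if g == group]

    def with_globals(self, **kwargs) -> "ModelParams":
        return ModelParams(replace(self.globals, **kwargs), dict(self.table))

    def noise_free(self) -> "ModelParams":
        """A copy with all stochastic heterogeneity channels switched off."""
        table = {
            key: replace(p, duration_sigma=0.0) for key, p in self.table.items()
        }
        return ModelParams(
            replace(self.globals, sigma_rate=0.0, window_offset_min=0.0,
                    daily_jitter_min=0.0),
            table,
        )


def _params_from_dict(raw: dict) -> ModelParams:
    g = dict(raw.get("global", {}))
    glob = GlobalParams(**g)
    table: dict[tuple[str, str], ActivityParams] = {}
    for group in GROUPS:
        for activity, entry in raw.get(group, {}).items():
            entry = dict(entry)
            entry["window_start"] = parse_clock(entry["window_start"])
            entry["window_end"] = parse_clock(entry["window_end"])
            table[(group, activity)] = ActivityParams(**entry)
    return ModelParams(glob, table)


def load_params(path: str | Path) -> ModelParams:
    """Load a parameter file (TOML)."""
    with open(path, "rb") as fh:
        return _params_from_dict(tomllib.load(fh))


def default_params() -> ModelParams:
    """The packaged default parameterisation (calibrated to UK time-use
    statistics for weekday activity participation and durations)."""
    ref = resources.files("surf.data").joinpath("params.toml")
    with ref.open("rb") as fh:
        return _params_from_dict(tomllib.load(fh))


def default_params_path() -> Path:
    return Path(str(resources.files("surf.data").joinpath("params.toml")))


def save_params(params: ModelParams, path: str | Path) -> None:
    """Write a parameter set as TOML (inverse of :func:`load_params`)."""
    g = params.globals
    lines = [
        "[global]",
        f"sigma_rate = {g.sigma_rate}",
        f"window_offset_min = {g.window_offset_min}",
        f"daily_jitter_min = {g.daily_jitter_min}",
        f"walking_speed_mps = {g.walking_speed_mps}",
        f"step_minutes = {g.step_minutes}",
        f"initial_radius_m = {g.initial_radius_m}",
        f"max_doublings = {g.max_doublings}",
    ]
    for (group, activity), p in sorted(params.table.items()):
        lines += [
            "",
            f"[{group}.{activity}]",
            f"grow_rate = {p.grow_rate}",
            f"decay_rate = {p.decay_rate}",
            f"amplitude = {p.amplitude}",
            f"baseline = {p.baseline}",
            f'window_start = "{format_clock(p.window_start)}"',
            f'window_end = "{format_clock(p.window_end)}"',
            f"min_duration_min = {p.min_duration_min}",
            f"duration_sigma = {p.duration_sigma}",
        ]
    Path(path).write_text("\n".join(lines) + "\n")
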