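"""Reported quantities: schedule statistics, hourly curves, comparisons.

Schedule statistics summarise final-day activity logs per demographic group:
the share of agents with at least one episode of an activity, and the mean
and median episode duration (an *episode* is a maximal contiguous run of one
activity; travel steps break runs and are excluded from durations).  These
are evaluated against packaged weekday time-use targets.

Footfall curves are standardised as Z-scores (population standard
deviation) so simulated and observed series share a scale; smoothing is a
locally-weighted linear fit and is purely presentational -- every metric is
computed on the raw hourly values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess

from .activities import ACTIVITIES, GROUPS, TRAVEL
from .sensors import FootfallTable

__all__ = [
    "ScheduleStats",
    "TargetSet",
    "schedule_stats",
    "evaluate_targets",
    "pooled_hourly_curve",
    "zscore",
    "smooth_curve",
    "compare",
    "compare_per_sensor",
    "ComparisonReport",
]


@dataclass
class ScheduleStats:
    """Per-(group, activity) participation and episode-duration statistics."""

    table: pd.DataFrame                      # indexed by (group, activity)
    start_hist: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    end_hist: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def get(self, group: str, activity: str, metric: str) -> float:
        return float(self.table.loc[(group, activity), metric])


def _episodes(log: np.ndarray):
    """Run-length encode one replicate's log.

    Returns arrays (agent_row, activity, start_step, length) over all
    maximal constant runs, excluding travel runs.
    """
    n, spd = log.shape
    if n == 0:
        return (np.zeros(0, int),) * 4
    sep = np.full((n, 1), -2, dtype=np.int8)
    flat = np.concatenate([log, sep], axis=1).ravel()
    change = np.flatnonzero(np.diff(flat)) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [flat.size]]))
    values = flat[starts]
    width = spd + 1
    rows = starts // width
    start_steps = starts % width
    keep = values >= 0
    return rows[keep], values[keep].astype(int), start_steps[keep], lengths[keep]


def schedule_stats(
    logs: np.ndarray | list[np.ndarray],
    groups: np.ndarray,
    step_minutes: float = 5.0,
) -> ScheduleStats:
    """Compute final-day schedule statistics, pooled over replicates.

    Parameters
    ----------
    logs : one ``(n_agents, steps_per_day)`` activity log or a list of them
        (one per replicate; all replicates share the agent ordering).
    groups : per-agent group index into ``GROUPS`` (or group-name array).
    """
    if isinstance(logs, np.ndarray):
        logs = [logs]
    if not logs or logs[0].size == 0:
        raise ValueError("empty activity logs")
    groups = np.asarray(groups)
    if groups.dtype.kind in "US":
        groups = np.array([GROUPS.index(g) for g in groups])

    rows_all, act_all, start_all, len_all, rep_all = [], [], [], [], []
    for r, log in enumerate(logs):
        rows, acts, starts, lengths = _episodes(np.asarray(log, dtype=np.int8))
        rows_all.append(rows)
        act_all.append(acts)
        start_all.append(starts)
        len_all.append(lengths)
        rep_all.append(np.full(rows.size, r))
    rows = np.concatenate(rows_all)
    acts = np.concatenate(act_all)
    starts = np.concatenate(start_all)
    lengths = np.concatenate(len_all)
    reps = np.concatenate(rep_all)

    records = []
    start_hist: dict[tuple[str, str], np.ndarray] = {}
    end_hist: dict[tuple[str, str], np.ndarray] = {}
    n_reps = len(logs)
    for gi, gname in enumerate(GROUPS):
        members = np.flatnonzero(groups == gi)
        if members.size == 0:
            continue
        member_mask = groups[rows] == gi
        for ai, aname in enumerate(ACTIVITIES):
            mask = member_mask & (acts == ai)
            n_episodes = int(mask.sum())
            if n_episodes == 0:
                continue
            # participation: distinct (replicate, agent) pairs with >= 1 episode
            pairs = reps[mask] * (groups.size + 1) + rows[mask]
            participants = np.unique(pairs).size
            participation = 100.0 * participants / (members.size * n_reps)
            durations = lengths[mask] * step_minutes
            sh = np.bincount(
                (starts[mask] * step_minutes // 60).astype(int), minlength=24
            )[:24]
            ends = ((starts[mask] + lengths[mask] - 1) * step_minutes // 60).astype(int)
            eh = np.bincount(ends, minlength=24)[:24]
            records.append(
                {
                    "group": gname,
                    "activity": aname,
                    "participation": participation,
                    "duration_mean": float(durations.mean()),
                    "duration_median": float(np.median(durations)),
                    "n_episodes": n_episodes,
                }
            )
            start_hist[(gname, aname)] = sh
            end_hist[(gname, aname)] = eh

    table = pd.DataFrame.from_records(records)
    if table.empty:
        raise ValueError("logs contain no performed activities")
    table = table.set_index(["group", "activity"])
    return ScheduleStats(table, start_hist, end_hist)


@dataclass
class TargetSet:
    """Named scalar calibration targets with tolerances."""

    table: pd.DataFrame  # columns group, activity, metric, value, tolerance, kind

    @classmethod
    def packaged(cls) -> "TargetSet":
        ref = resources.files("surf.data").joinpath("uktus_targets.csv")
        with ref.open() as fh:
            df = pd.read_csv(fh)
        if (df["tolerance"] <= 0).any():
            raise ValueError("target tolerances must be > 0")
        return cls(df)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TargetSet":
        return cls(pd.read_csv(path))


def evaluate_targets(stats: ScheduleStats, targets: TargetSet | None = None
                     ) -> pd.DataFrame:
    """Compare schedule statistics against the calibration targets.

    Returns one row per target with the simulated value, the deviation and a
    pass flag (absolute tolerance for ``kind == 'abs'``, relative for
    ``'rel'``).  Raises if the statistics do not cover a targeted pair.
    """
    targets = targets or TargetSet.packaged()
    rows = []
    for _, tr in targets.table.iterrows():
        key = (tr["group"], tr["activity"])
        if key not in stats.table.index:
            raise KeyError(f"statistics missing targeted pair {key}")
        sim = stats.get(tr["group"], tr["activity"], tr["metric"])
        dev = sim - tr["value"]
        tol = tr["tolerance"] * (abs(tr["value"]) if tr["kind"] == "rel" else 1.0)
        rows.append(
            {
                "group": tr["group"],
                "activity": tr["activity"],
                "metric": tr["metric"],
                "target": tr["value"],
                "simulated": sim,
                "abs_deviation": abs(dev),
                "rel_deviation": abs(dev) / abs(tr["value"]) if tr["value"] else np.nan,
                "tolerance": tol,
                "passed": abs(dev) <= tol,
            }
        )
    return pd.DataFrame(rows)


def pooled_hourly_curve(table: FootfallTable) -> np.ndarray:
    """Mean footfall across sensors at each hour (a 24-vector)."""
    return np.asarray(table.counts, dtype=float).mean(axis=0)


def zscore(series) -> np.ndarray:
    """Standardise a series: (x - mean) / sd with the population sd."""
    x = np.asarray(series, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("constant series has no Z-score")
    return (x - x.mean()) / sd


def smooth_curve(series, bandwidth: float = 0.3) -> np.ndarray:
    """Locally-weighted linear smooth of an hourly curve.

    ``bandwidth`` is the fraction of points in each local fit.  Presentation
    only: comparison metrics always use raw values.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    y = np.asarray(series, dtype=float)
    x = np.arange(y.size, dtype=float)
    frac = min(1.0, bandwidth)
    return lowess(y, x, frac=frac, it=0, return_sorted=False)


@dataclass
class ComparisonReport:
    """Simulated-versus-observed hourly footfall comparison (on Z-scores)."""

    z_sim: np.ndarray
    z_obs: np.ndarray
    residual: np.ndarray        # z_obs - z_sim
    rmse: float
    pearson_r: float
    sim_smooth: np.ndarray
    obs_smooth: np.ndarray


def compare(sim_curve, obs_curve, bandwidth: float = 0.3) -> ComparisonReport:
    """Compare two 24-hour curves after Z-score standardisation."""
    sim = np.asarray(sim_curve, dtype=float)
    obs = np.asarray(obs_curve, dtype=float)
    if sim.shape != obs.shape:
        raise ValueError("curves must have equal length")
    zs, zo = zscore(sim), zscore(obs)
    residual = zo - zs
    rmse = float(np.sqrt(np.mean(residual ** 2)))
    r = float(sps.pearsonr(zs, zo).statistic)
    return ComparisonReport(
        z_sim=zs,
        z_obs=zo,
        residual=residual,
        rmse=rmse,
        pearson_r=r,
        sim_smooth=smooth_curve(zs, bandwidth),
        obs_smooth=smooth_curve(zo, bandwidth),
    )


def compare_per_sensor(
    sim: FootfallTable, obs: FootfallTable, bandwidth: float = 0.3
) -> dict[str, ComparisonReport]:
    """Per-sensor comparison of simulated and observed hourly footfall."""
    out = {}
    obs_idx = {sid: i for i, sid in enumerate(obs.sensor_ids)}
    for i, sid in enumerate(sim.sensor_ids):
        if sid not in obs_idx:
            raise KeyError(f"observed table has no sensor {sid!r}")
        out[sid] = compare(sim.counts[i], obs.counts[obs_idx[sid]], bandwidth)
    return out
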