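"""Virtual footfall sensors.

A sensor counts one event each time an agent's movement *enters* its
detection disc from outside (remaining inside across steps does not
re-count, mirroring how a Wi-Fi sensor registers a passing device once).
Entries are computed geometrically on the straight segments of the movement
polyline, so a step that jumps clean across a small disc is still counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .environment import Sensor

__all__ = [
    "segment_disc_entry",
    "polyline_disc_entries",
    "record_crossings",
    "hourly_totals",
    "FootfallTable",
]


def segment_disc_entry(p0, p1, centre, radius: float) -> float | None:
    """Arc length along segment ``p0 -> p1`` at which it first enters the disc.

    Returns ``None`` if the segment starts inside the disc or never reaches
    it.  The boundary counts as inside.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    c = np.asarray(centre, dtype=float)
    d = p1 - p0
    f = p0 - c
    if f @ f <= radius * radius:  # starts inside: no entry on this segment
        return None
    a = d @ d
    if a == 0.0:
        return None
    b = 2.0 * (f @ d)
    cc = f @ f - radius * radius
    disc = b * b - 4.0 * a * cc
    if disc < 0.0:
        return None
    t = (-b - np.sqrt(disc)) / (2.0 * a)
    if 0.0 <= t <= 1.0:
        return float(t * np.sqrt(a))
    return None


def polyline_disc_entries(points: np.ndarray, centre, radius: float) -> list[float]:
    """Arc lengths at which a polyline enters a disc (possibly repeatedly)."""
    points = np.asarray(points, dtype=float)
    entries: list[float] = []
    arc = 0.0
    for i in range(len(points) - 1):
        p0, p1 = points[i], points[i + 1]
        e = segment_disc_entry(p0, p1, centre, radius)
        if e is not None:
            entries.append(arc + e)
        arc += float(np.linalg.norm(p1 - p0))
    return entries


def record_crossings(
    pos_t,
    pos_t1,
    sensors: list[Sensor],
    was_inside: np.ndarray | None = None,
) -> tuple[list[int], np.ndarray]:
    """Crossing events generated by one movement step.

    Parameters
    ----------
    pos_t, pos_t1 : positions at the start and end of the step.
    sensors : the sensors to test.
    was_inside : boolean per-sensor state from the previous step (an agent
        already inside a disc produces no event until it leaves and
        re-enters).  Defaults to "inside iff the start position is inside",
        so an agent that begins the simulation inside a disc is not counted.

    Returns the indices of sensors entered during the step and the updated
    inside/outside state.
    """
    p0 = np.asarray(pos_t, dtype=float)
    p1 = np.asarray(pos_t1, dtype=float)
    events: list[int] = []
    now_inside = np.zeros(len(sensors), dtype=bool)
    for i, s in enumerate(sensors):
        c = np.array(s.xy)
        r = s.radius_m
        inside0 = (
            bool(was_inside[i])
            if was_inside is not None
            else bool((p0 - c) @ (p0 - c) <= r * r)
        )
        inside1 = bool((p1 - c) @ (p1 - c) <= r * r)
        entered = False
        if not inside0:
            entered = segment_disc_entry(p0, p1, c, r) is not None
        if entered:
            events.append(i)
        now_inside[i] = inside1
    return events, now_inside


def hourly_totals(
    events: list[tuple[float, int | str]],
    sensor_ids: list[str],
    day_start_min: float = 0.0,
) -> "FootfallTable":
    """Bin timestamped crossing events into hourly counts for one day.

    ``events`` are ``(time_min, sensor)`` pairs with times inside
    ``[day_start_min, day_start_min + 1440)``; sensors may be referenced by
    index or id.
    """
    counts = np.zeros((len(sensor_ids), 24), dtype=int)
    index = {sid: i for i, sid in enumerate(sensor_ids)}
    for t, s in events:
        rel = t - day_start_min
        if not 0.0 <= rel < 1440.0:
            raise ValueError(f"event at {t} min outside the reported day")
        i = s if isinstance(s, (int, np.integer)) else index[s]
        counts[i, int(rel // 60.0)] += 1
    return FootfallTable(counts=counts, sensor_ids=list(sensor_ids))


@dataclass
class FootfallTable:
    """Hourly footfall counts per sensor for one reported day.

    ``counts`` holds a single day's (or the replicate-mean) sensor-by-hour
    table; ``replicates`` optionally stacks per-replicate tables, with
    bootstrap confidence bounds in ``ci_lo``/``ci_hi``.
    """

    counts: np.ndarray                 # (S, 24)
    sensor_ids: list[str]
    replicates: np.ndarray | None = None   # (R, S, 24)
    ci_lo: np.ndarray | None = None
    ci_hi: np.ndarray | None = None
    ci_level: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.sensor_ids), 24):
            raise ValueError("counts must have shape (n_sensors, 24)")
        if (self.counts < 0).any():
            raise ValueError("footfall counts must be >= 0")

    @property
    def n_replicates(self) -> int:
        return 0 if self.replicates is None else self.replicates.shape[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, sid in enumerate(self.sensor_ids):
            for h in range(24):
                row = {"sensor_id": sid, "hour": h, "count": self.counts[i, h]}
                if self.ci_lo is not None:
                    row["ci_lo"] = self.ci_lo[i, h]
                    row["ci_hi"] = self.ci_hi[i, h]
                rows.append(row)
        return pd.DataFrame(rows)

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FootfallTable":
        df = pd.read_csv(path)
        sensors = sorted(df["sensor_id"].astype(str).unique())
        counts = np.zeros((len(sensors), 24))
        idx = {s: i for i, s in enumerate(sensors)}
        for _, row in df.iterrows():
            counts[idx[str(row["sensor_id"])], int(row["hour"])] = row["count"]
        return cls(counts=counts, sensor_ids=sensors)
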