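"""Spatial allocation of flexible activities.

A flexible activity happens at a uniformly random building with the correct
function within a search radius of the agent's previous location; the radius
doubles iteratively until at least one candidate is found.  Anchored
activities (home, work) bypass allocation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activities import ACTIVITIES, ACTIVITY_FUNCTION, ACTIVITY_TYPES
from .environment import Building, Town

__all__ = ["AllocationPolicy", "AllocationError", "allocate_location", "BuildingIndex"]


class AllocationError(RuntimeError):
    """No suitable building within the maximal search radius."""


@dataclass(frozen=True)
class AllocationPolicy:
    initial_radius_m: float = 500.0
    max_doublings: int = 6

    def __post_init__(self) -> None:
        if self.initial_radius_m <= 0:
            raise ValueError("initial_radius_m must be > 0")
        if self.max_doublings < 0:
            raise ValueError("max_doublings must be >= 0")


class BuildingIndex:
    """Distance queries over a town's buildings, grouped by function."""

    def __init__(self, town: Town):
        self._by_function: dict[str, tuple[list[Building], np.ndarray]] = {}
        for fn, blds in town.buildings_by_function.items():
            coords = np.array([[b.x, b.y] for b in blds], dtype=float).reshape(-1, 2)
            self._by_function[fn] = (blds, coords)

    def within(self, function: str, xy, radius_m: float) -> list[Building]:
        blds, coords = self._by_function[function]
        if not blds:
            return []
        d2 = np.sum((coords - np.asarray(xy, dtype=float)) ** 2, axis=1)
        return [b for b, ok in zip(blds, d2 <= radius_m ** 2) if ok]

    def allocate(
        self,
        function: str,
        xy,
        policy: AllocationPolicy,
        rng: np.random.Generator,
    ) -> Building:
        """Uniform choice within the smallest non-empty doubled radius."""
        radius = policy.initial_radius_m
        for _ in range(policy.max_doublings + 1):
            candidates = self.within(function, xy, radius)
            if candidates:
                return candidates[int(rng.integers(len(candidates)))]
            radius *= 2.0
        raise AllocationError(
            f"no {function!r} building within "
            f"{policy.initial_radius_m * 2 ** policy.max_doublings:.0f} m"
        )


def _town_index(town: Town) -> BuildingIndex:
    idx = getattr(town, "_building_index", None)
    if idx is None:
        idx = BuildingIndex(town)
        town._building_index = idx  # type: ignore[attr-defined]
    return idx


def allocate_location(
    town: Town,
    activity: str | int,
    from_point,
    policy: AllocationPolicy | None = None,
    rng: np.random.Generator | None = None,
    agent=None,
) -> Building:
    """Choose the building where a flexible activity takes place.

    For anchored activities the agent's anchor building is returned (``agent``
    must then carry ``home_building``/``work_building``).
    """
    if isinstance(activity, int):
        activity = ACTIVITIES[activity]
    atype = ACTIVITY_TYPES[ACTIVITIES.index(activity)]
    if atype.anchored:
        if agent is None:
            raise ValueError(f"{activity} is anchored; an agent is required")
        bid = agent.home_building if activity == "at_home" else agent.work_building
        return town.building_by_id[bid]
    if policy is None:
        policy = AllocationPolicy()
    if rng is None:
        rng = np.random.default_rng()
    return _town_index(town).allocate(
        ACTIVITY_FUNCTION[activity], from_point, policy, rng
    )
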