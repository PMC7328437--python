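"""Activity vocabulary shared by the whole model.

Seven activities drive agent behaviour: being at home, working in an office
(commuters only), shopping for food, leisure shopping (retired only), having
lunch out, an evening food/drink social activity, and sports.  Each
away-from-home flexible activity maps to exactly one building function;
``at_home`` and ``work`` use the agent's anchor buildings instead.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Canonical activity order.  Ties between equally intense candidate
#: activities are broken by this order (lowest index wins).
ACTIVITIES: tuple[str, ...] = (
    "at_home",
    "work",
    "shop_food",
    "shop_leisure",
    "lunch_out",
    "evening_social",
    "sports",
)

AT_HOME, WORK, SHOP_FOOD, SHOP_LEISURE, LUNCH_OUT, EVENING_SOCIAL, SPORTS = range(7)

#: Log code for a travelling step (never a performed activity).
TRAVEL: int = -1

GROUPS: tuple[str, ...] = ("commuter", "retired")

#: Building function required by each flexible activity.
ACTIVITY_FUNCTION: dict[str, str] = {
    "shop_food": "supermarket",
    "shop_leisure": "leisure_shop",
    "lunch_out": "restaurant",
    "evening_social": "pub",
    "sports": "sports_facility",
}

BUILDING_FUNCTIONS: tuple[str, ...] = (
    "residential",
    "office",
    "supermarket",
    "leisure_shop",
    "restaurant",
    "pub",
    "sports_facility",
)

#: Which groups perform which activity.
ACTIVITY_GROUPS: dict[str, tuple[str, ...]] = {
    "at_home": ("commuter", "retired"),
    "work": ("commuter",),
    "shop_food": ("commuter", "retired"),
    "shop_leisure": ("retired",),
    "lunch_out": ("commuter", "retired"),
    "evening_social": ("commuter", "retired"),
    "sports": ("commuter", "retired"),
}


@dataclass(frozen=True)
class ActivityType:
    """One of the seven modelled activities."""

    name: str
    required_function: str | None
    groups: tuple[str, ...]

    @property
    def anchored(self) -> bool:
        """True for activities performed at a fixed anchor building."""
        return self.required_function is None


ACTIVITY_TYPES: tuple[ActivityType, ...] = tuple(
    ActivityType(name, ACTIVITY_FUNCTION.get(name), ACTIVITY_GROUPS[name])
    for name in ACTIVITIES
)


def activity_index(name: str) -> int:
    try:
        return ACTIVITIES.index(name)
    except ValueError:
        raise KeyError(f"unknown activity {name!r}") from None


def activities_for(group: str) -> list[int]:
    """Indices of the activities applicable to a demographic group."""
    if group not in GROUPS:
        raise KeyError(f"unknown group {group!r}")
    return [i for i, a in enumerate(ACTIVITY_TYPES) if group in a.groups]
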