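"""Food-source scoring and area-standardized census densities.

Free-ranging dogs scavenge almost exclusively from anthropogenic food
sources.  Each mapped source belongs to one of eight categories carrying an
ordinal quality/quantity score from 8 (open-air meat or fish shop) down to 1
(uncovered household dustbin).  A survey polygon's *resource density* is the
sum of its point scores divided by polygon area (score ha^-1); *dog density*
is the census dog count divided by area (dogs ha^-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Optional, Sequence

from .geometry import GeometryError, Point2D, Polygon2D, polygon_area_ha

__all__ = [
    "ResourceCategory",
    "CATEGORY_SCORES",
    "CATEGORY_LABELS",
    "ResourcePoint",
    "DogRecord",
    "CensusSite",
    "score_sum",
    "resource_density",
    "dog_density",
]


class ResourceCategory(IntEnum):
    """The eight food-source categories, coded 1-8.

    Codes follow the field scoring sheet ordering (1 = highest-scoring
    source); the ``score`` property returns the quality/quantity score.
    """

    MEAT_FISH_SHOP = 1
    EATERY_RESTAURANT_HOSTEL = 2
    DIRECT_FEEDING_HUMAN_NGO = 3
    GARBAGE_DUMP_CARCASS = 4
    TEA_SHOP_TEMPLE = 5
    DIRECT_FEEDING_BEGGING = 6
    GROCERY_SWEET_BAKERY = 7
    HOUSEHOLD_EATERY_DUSTBIN = 8

    @property
    def score(self) -> int:
        return CATEGORY_SCORES[self]

    @property
    def label(self) -> str:
        return CATEGORY_LABELS[self]


CATEGORY_SCORES: dict[ResourceCategory, int] = {
    ResourceCategory.MEAT_FISH_SHOP: 8,
    ResourceCategory.EATERY_RESTAURANT_HOSTEL: 7,
    ResourceCategory.DIRECT_FEEDING_HUMAN_NGO: 6,
    ResourceCategory.GARBAGE_DUMP_CARCASS: 5,
    ResourceCategory.TEA_SHOP_TEMPLE: 4,
    ResourceCategory.DIRECT_FEEDING_BEGGING: 3,
    ResourceCategory.GROCERY_SWEET_BAKERY: 2,
    ResourceCategory.HOUSEHOLD_EATERY_DUSTBIN: 1,
}

CATEGORY_LABELS: dict[ResourceCategory, str] = {
    ResourceCategory.MEAT_FISH_SHOP: "Meat shop or fish shop",
    ResourceCategory.EATERY_RESTAURANT_HOSTEL: "Eatery/restaurant/hostel",
    ResourceCategory.DIRECT_FEEDING_HUMAN_NGO: "Direct feeding by human or NGO",
    ResourceCategory.GARBAGE_DUMP_CARCASS: "Open garbage dump or occasional carcass",
    ResourceCategory.TEA_SHOP_TEMPLE: "Tea shop or temple",
    ResourceCategory.DIRECT_FEEDING_BEGGING: "Direct feeding by human (begging)",
    ResourceCategory.GROCERY_SWEET_BAKERY: "Grocery/sweet shop/bakery",
    ResourceCategory.HOUSEHOLD_EATERY_DUSTBIN: "Household or eatery dustbins (without cover)",
}


@dataclass(frozen=True)
class ResourcePoint:
    """A located, categorized food source."""

    id: str
    location: Point2D
    category: ResourceCategory

    @property
    def score(self) -> int:
        return self.category.score


@dataclass(frozen=True)
class DogRecord:
    """One censused dog: sex M/F/U, age class, and observed group size."""

    sex: str = "U"
    age_class: str = "adult"
    group_size: int = 1

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F", "U"):
            raise ValueError(f"sex must be M/F/U, got {self.sex!r}")
        if self.age_class not in ("pup", "juvenile", "adult"):
            raise ValueError(f"age_class must be pup/juvenile/adult, got {self.age_class!r}")


SANE_AREA_RANGE_HA = (1.29, 161.0)  # observed survey-polygon range; outside -> warning


@dataclass
class CensusSite:
    """A census survey polygon with its settlement stratum, dogs, and resources.

    Settlement is ``"urban"`` (municipality/corporation town) or ``"rural"``
    (gram-panchayat village).  Pups are included in census dog counts.
    """

    id: str
    polygon: Polygon2D
    settlement: str
    resource_points: list[ResourcePoint] = field(default_factory=list)
    dog_records: list[DogRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.settlement not in ("urban", "rural"):
            raise ValueError(f"settlement must be 'urban' or 'rural', got {self.settlement!r}")
        area = self.area_ha
        lo, hi = SANE_AREA_RANGE_HA
        if not (lo <= area <= hi):
            warnings.warn(
                f"site {self.id}: area {area:.2f} ha outside the typical survey range "
                f"[{lo}, {hi}] ha",
                stacklevel=2,
            )
        outside = 0
        if self.resource_points:
            import shapely

            xs = [rp.location.x for rp in self.resource_points]
            ys = [rp.location.y for rp in self.resource_points]
            outside = int((~shapely.intersects_xy(self.polygon.shapely, xs, ys)).sum())
        if outside:
            warnings.warn(
                f"site {self.id}: {outside} resource point(s) fall outside the polygon "
                "(boundary GPS noise?)",
                stacklevel=2,
            )

    @property
    def area_ha(self) -> float:
        return polygon_area_ha(self.polygon)

    @property
    def dog_count(self) -> int:
        return len(self.dog_records)


def score_sum(points: Iterable[ResourcePoint]) -> int:
    """Sum of category scores over resource points (0 for an empty set)."""
    return sum(p.score for p in points)


def resource_density(site: CensusSite) -> float:
    """Area-standardized resource score: (sum_j s_j) / A, in score ha^-1."""
    area = site.area_ha
    if area <= 0:
        raise GeometryError(f"site {site.id}: non-positive area")
    return score_sum(site.resource_points) / area


def dog_density(site: CensusSite, sex: Optional[str] = None) -> float:
    """Dogs per hectare; restrict to one sex with ``sex='M'|'F'|'U'``.

    The male, female and unsexed densities partition the total.
    """
    area = site.area_ha
    if area <= 0:
        raise GeometryError(f"site {site.id}: non-positive area")
    if sex is None:
        count = len(site.dog_records)
    else:
        if sex not in ("M", "F", "U"):
            raise ValueError(f"sex filter must be M/F/U, got {sex!r}")
        count = sum(1 for d in site.dog_records if d.sex == sex)
    return count / area


def category_table() -> "list[dict]":
    """Machine-readable scoring table (code, label, score) for serialization."""
    return [
        {"code": int(cat), "label": cat.label, "score": cat.score}
        for cat in ResourceCategory
    ]
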