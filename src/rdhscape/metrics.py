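"""Territory-level resource statistics.

Three summaries of a territory's food-resource layout drive the
resource-dispersion analyses:

* **patch richness** — the number of resource points in the territory;
* **heterogeneity** — the number of distinct food-source categories present
  (0-8);
* **dispersion** — for each point, its mean distance to the other points;
  averaged over points.  With the default N-1 divisor this equals the mean
  pairwise inter-point distance, and a two-point layout returns their actual
  separation.  Undefined for fewer than two points (NaN; rows are dropped
  listwise by the model fitters, with a logged count).

Group composition enters the models through the male:female ratio, undefined
for all-male groups (NaN, same listwise policy).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import Point2D, Polygon2D, convex_hull, pairwise_distances, polygon_area_ha
from .scoring import ResourcePoint

__all__ = [
    "SEASONS",
    "TerritoryRecord",
    "ResourceMetrics",
    "patch_richness",
    "heterogeneity",
    "dispersion",
    "mf_ratio",
    "compute_metrics",
]

logger = logging.getLogger(__name__)

#: The three reproductive seasons, in annual order:
#: pre-mating (April-early July), mating (mid July-mid October),
#: post-mating pup emergence (late October-March).
SEASONS = ("pre_mating", "mating", "post_mating")


@dataclass
class TerritoryRecord:
    """One dog group in one season: boundary, resources, composition.

    The territory polygon is the convex hull of the recorded marking/defence
    boundary points unless an explicit polygon is supplied.  Adults must be
    fully sexed: ``n_adults = n_male + n_female``.
    """

    group_id: str
    season: str
    boundary_points: list[Point2D] = field(default_factory=list)
    resource_points: list[ResourcePoint] = field(default_factory=list)
    n_male: int = 0
    n_female: int = 0
    n_pups: int = 0
    territory: Optional[Polygon2D] = None

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValueError(f"season must be one of {SEASONS}, got {self.season!r}")
        if self.n_male < 0 or self.n_female < 0 or self.n_pups < 0:
            raise ValueError("counts must be non-negative")
        if self.territory is None:
            if len(self.boundary_points) < 3:
                raise ValueError(
                    f"group {self.group_id}/{self.season}: need >=3 boundary points "
                    "or an explicit territory polygon"
                )
            self.territory = convex_hull(self.boundary_points)

    @property
    def n_adults(self) -> int:
        return self.n_male + self.n_female

    @property
    def area_ha(self) -> float:
        assert self.territory is not None
        return polygon_area_ha(self.territory)


@dataclass(frozen=True)
class ResourceMetrics:
    """The per-territory summary row consumed by the territory models."""

    patch_richness: int
    heterogeneity: int
    dispersion: float  # metres; NaN when undefined (<2 points)
    territory_area: float  # hectares
    mf_ratio: float  # NaN when undefined (0 females)


def patch_richness(t: TerritoryRecord) -> int:
    """Number of food resource points in the territory (duplicates count)."""
    return len(t.resource_points)


def heterogeneity(t: TerritoryRecord) -> int:
    """Number of distinct food-source categories present (0-8)."""
    return len({p.category for p in t.resource_points})


def dispersion(t: TerritoryRecord, divisor: str = "n_minus_1") -> float:
    """Mean per-point average distance to the other resource points, metres.

    Parameters
    ----------
    divisor:
        ``"n_minus_1"`` (default) excludes the zero self-distance from each
        point's average, making the statistic exactly the mean pairwise
        distance.  ``"n"`` divides each point's distance sum by N instead,
        shrinking every average by (N-1)/N; exposed so either published
        convention can be reproduced.

    Returns NaN when fewer than two points are present.
    """
    n = len(t.resource_points)
    if n < 2:
        logger.warning(
            "group %s/%s: dispersion undefined with %d resource point(s)",
            t.group_id, t.season, n,
        )
        return math.nan
    d = pairwise_distances([p.location for p in t.resource_points])
    # mean over points i of (sum_{j != i} d_ij / divisor); each unordered pair
    # appears in two per-point sums, so the grand sum is 2 * sum(d).
    if divisor == "n_minus_1":
        return float(2.0 * d.sum() / (n * (n - 1)))
    if divisor == "n":
        return float(2.0 * d.sum() / (n * n))
    raise ValueError(f"divisor must be 'n_minus_1' or 'n', got {divisor!r}")


def mf_ratio(t: TerritoryRecord) -> float:
    """Adult male:female ratio; NaN (excluded downstream) when no females."""
    if t.n_female == 0:
        logger.warning(
            "group %s/%s: male:female ratio undefined (no adult females)",
            t.group_id, t.season,
        )
        return math.nan
    return t.n_male / t.n_female


def compute_metrics(t: TerritoryRecord, divisor: str = "n_minus_1") -> ResourceMetrics:
    """All five territory summaries in one row (NaN for undefined entries)."""
    return ResourceMetrics(
        patch_richness=patch_richness(t),
        heterogeneity=heterogeneity(t),
        dispersion=dispersion(t, divisor=divisor),
        territory_area=t.area_ha,
        mf_ratio=mf_ratio(t),
    )


def metrics_frame(records: Sequence[TerritoryRecord], divisor: str = "n_minus_1"):
    """Tabulate records as a pandas DataFrame, one row per group x season."""
    import pandas as pd

    rows = []
    for t in records:
        m = compute_metrics(t, divisor=divisor)
        rows.append(
            {
                "group_id": t.group_id,
                "season": t.season,
                "n_male": t.n_male,
                "n_female": t.n_female,
                "n_pups": t.n_pups,
                "n_adults": t.n_adults,
                "patch_richness": m.patch_richness,
                "heterogeneity": m.heterogeneity,
                "dispersion": m.dispersion,
                "territory_area": m.territory_area,
                "mf_ratio": m.mf_ratio,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["season"] = pd.Categorical(df["season"], categories=list(SEASONS))
    return df
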