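import numpy as np
import pytest

from rdhscape import Point2D, Polygon2D, ResourceCategory, ResourcePoint, TerritoryRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def unit_square_ha():
    """100 m x 100 m square (1 ha) with a corner at the origin."""
    return Polygon2D([Point2D(0, 0), Point2D(100, 0), Point2D(100, 100), Point2D(0, 100)])


def make_points(coords, categories=None):
    categories = categories or [1] * len(coords)
    return [
        ResourcePoint(id=f"p{i}", location=Point2D(x, y), category=ResourceCategory(c))
        for i, ((x, y), c) in enumerate(zip(coords, categories))
    ]


@pytest.fixture
def square_territory(unit_square_ha):
    """Unit-square territory with 4 corner resources of distinct categories."""
    pts = make_points(
        [(0, 0), (100, 0), (100, 100), (0, 100)],
        [ResourceCategory.MEAT_FISH_SHOP, ResourceCategory.EATERY_RESTAURANT_HOSTEL,
         ResourceCategory.GARBAGE_DUMP_CARCASS, ResourceCategory.HOUSEHOLD_EATERY_DUSTBIN],
    )
    return TerritoryRecord(
        group_id="g0", season="mating", resource_points=pts,
        n_male=2, n_female=2, territory=unit_square_ha,
    )
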