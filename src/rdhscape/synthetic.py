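"""Synthetic landscapes, censuses and territory panels.

The generator produces data with the statistical structure the analyses
assume, so every pipeline stage can be exercised and calibrated end to end:

* survey polygons spanning the observed 1.29-161 ha range, labelled
  urban/rural;
* food-resource point layouts from Poisson, Matern-cluster or hard-core
  processes (spanning the dispersion gradient from clumped to regular), with
  category draws from per-settlement weight vectors;
* census dog densities following the Gamma log-link interaction structure
  (dog density ~ resource density x settlement), discretized to whole dogs
  so the stored count/area pair is self-consistent;
* a group x season territory panel whose territory areas follow the
  five-predictor Gamma log-link truth with a group random intercept and
  seasonal contraction, and whose adult counts are intercept-only Gamma
  noise (the no-effect truth for the group-size model).

Default effect sizes are the published point estimates of the models the
pipeline refits; nuisance settings (dispersions, layout ranges, category
weights) are chosen to produce realistic field-scale data and are documented
in the methods note.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import Point2D, Polygon2D, polygon_area_ha
from .metrics import SEASONS, TerritoryRecord
from .scoring import CensusSite, DogRecord, ResourceCategory, ResourcePoint

__all__ = [
    "CensusTruth",
    "TerritoryTruth",
    "SimConfig",
    "gen_polygon",
    "gen_resources",
    "gen_census",
    "gen_territory_panel",
    "gen_metric_panel",
]

#: mean Table-style score under uniform category weights
_UNIFORM_WEIGHTS = tuple([1.0 / 8] * 8)


@dataclass
class CensusTruth:
    """Generating coefficients of the census Gamma GLM (log scale).

    Defaults are the fitted interaction-model point estimates: intercept,
    rural resource slope, urban main effect, resource x urban interaction.
    ``dispersion`` is the Gamma dispersion phi (Var = phi mu^2) of dog
    density around its modelled mean.
    """

    intercept: float = -0.346
    resource_slope: float = 0.110
    urban: float = 1.169
    interaction: float = -0.106
    dispersion: float = 0.35


@dataclass
class TerritoryTruth:
    """Generating coefficients for the territory panel.

    ``area_coefs`` follow the territory-size model term order
    (intercept, n_adults, heterogeneity, patch_richness, mf_ratio,
    dispersion); defaults are the published point estimates.  Adult counts
    are intercept-only (the group-size null finding).  Season effects are
    log-scale contrasts vs the mating season.
    """

    area_coefs: tuple = (-2.788, -0.0006, 0.102, 0.041, 0.391, 0.0206)
    area_dispersion: float = 0.012
    season_effects: dict = field(
        default_factory=lambda: {"pre_mating": -0.02, "mating": 0.0, "post_mating": -0.08}
    )
    group_sd: float = 0.423
    adults_intercept: float = 1.776
    adults_dispersion: float = 0.20


@dataclass
class SimConfig:
    """All generator parameters; the seed fully determines output."""

    seed: int = 0
    # --- census block ---
    n_rural: int = 52
    n_urban: int = 41
    area_range_ha: tuple = (1.29, 161.0)
    #: mean resource points per hectare by settlement (score/ha targets of
    #: ~4.1 rural and ~10.3 urban at mean point score 4.5)
    resource_intensity: dict = field(default_factory=lambda: {"rural": 0.92, "urban": 2.28})
    #: between-site spread of log resource intensity (right-skewed densities)
    intensity_log_sd: float = 0.8
    category_weights: dict = field(
        default_factory=lambda: {"rural": _UNIFORM_WEIGHTS, "urban": _UNIFORM_WEIGHTS}
    )
    point_process: str = "poisson"  # poisson | clustered | regular
    cluster_radius: float = 30.0  # m, Matern offspring disk
    offspring_mean: float = 4.0
    inhibition: float = 25.0  # m, hard-core distance
    frac_female: float = 0.5
    age_class_probs: tuple = (0.70, 0.15, 0.15)  # adult, juvenile, pup
    census_truth: CensusTruth = field(default_factory=CensusTruth)
    # --- territory block ---
    n_groups: int = 36
    seasons: tuple = SEASONS
    panel_size: Optional[int] = 84  # rows retained after random missingness
    richness_mean_range: tuple = (5.0, 25.0)  # per-group mean resource count
    layout_radius_range: tuple = (40.0, 130.0)  # m, spatial scale of layouts
    categories_range: tuple = (2, 8)  # per-group available category counts
    pups_post_mating_mean: float = 3.0
    territory_truth: TerritoryTruth = field(default_factory=TerritoryTruth)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "census_truth" in d and isinstance(d["census_truth"], dict):
            d["census_truth"] = CensusTruth(**d["census_truth"])
        if "territory_truth" in d and isinstance(d["territory_truth"], dict):
            tt = dict(d["territory_truth"])
            if "area_coefs" in tt:
                tt["area_coefs"] = tuple(tt["area_coefs"])
            d["territory_truth"] = TerritoryTruth(**tt)
        for key in ("area_range_ha", "age_class_probs", "seasons", "richness_mean_range",
                    "layout_radius_range", "categories_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "category_weights" in d:
            d["category_weights"] = {
                k: tuple(v) for k, v in d["category_weights"].items()
            }
        return cls(**d)


# ---------------------------------------------------------------------------
# geometry generation


def gen_polygon(
    area_ha: float,
    rng: np.random.Generator,
    center: tuple[float, float] = (0.0, 0.0),
    n_vertices: int = 10,
    irregularity: float = 0.35,
) -> Polygon2D:
    """A simple random polygon of (almost exactly) the requested area.

    A star-convex ring is drawn by perturbing vertex radii around a circle,
    then rescaled so its shoelace area matches ``area_ha`` exactly; the
    perturbation keeps shapes irregular but simple (non-self-intersecting).
    """
    if area_ha <= 0:
        raise ValueError("area_ha must be positive")
    # distinct angles with no gap beyond ~pi: edges then stay inside disjoint
    # angular wedges around the center, guaranteeing a simple ring
    while True:
        angles = np.sort(rng.uniform(0.0, 2.0 * np.pi, n_vertices))
        gaps = np.diff(np.concatenate([angles, [angles[0] + 2 * np.pi]]))
        if gaps.min() > 1e-3 and gaps.max() < 2.8:
            break
    radii = 1.0 + irregularity * rng.uniform(-1.0, 1.0, n_vertices)
    x = radii * np.cos(angles)
    y = radii * np.sin(angles)
    raw_area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    scale = math.sqrt(area_ha * 10_000.0 / raw_area)
    cx, cy = center
    return Polygon2D([Point2D(cx + scale * xi, cy + scale * yi) for xi, yi in zip(x, y)])


def _uniform_in_polygon(poly: Polygon2D, n: int, rng: np.random.Generator) -> list[Point2D]:
    import shapely

    minx, miny, maxx, maxy = poly.shapely.bounds
    out: list[Point2D] = []
    while len(out) < n:
        m = max(16, 2 * (n - len(out)))
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        inside = shapely.contains_xy(poly.shapely, xs, ys)
        for xi, yi in zip(xs[inside], ys[inside]):
            out.append(Point2D(float(xi), float(yi)))
            if len(out) == n:
                break
    return out


def gen_resources(
    poly: Polygon2D,
    intensity: float,
    rng: np.random.Generator,
    process: str = "poisson",
    category_weights: Sequence[float] = _UNIFORM_WEIGHTS,
    cluster_radius: float = 30.0,
    offspring_mean: float = 4.0,
    inhibition: float = 25.0,
    id_prefix: str = "r",
) -> list[ResourcePoint]:
    """Resource points inside a polygon from a chosen point process.

    ``intensity`` is the expected number of points per hectare.  The
    clustered (Matern parent-offspring) process concentrates points within
    ``cluster_radius`` of Poisson parents, lowering mean inter-point
    distance at equal intensity; the regular (hard-core) process thins a
    Poisson proposal to a minimum separation of ``inhibition`` metres,
    raising it.
    """
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    area = polygon_area_ha(poly)
    expected = intensity * area
    locations: list[Point2D]
    if process == "poisson":
        n = rng.poisson(expected)
        locations = _uniform_in_polygon(poly, n, rng)
    elif process == "clustered":
        n_parents = rng.poisson(max(expected / offspring_mean, 1e-12))
        parents = _uniform_in_polygon(poly, n_parents, rng)
        locations = []
        for par in parents:
            k = rng.poisson(offspring_mean)
            r = cluster_radius * np.sqrt(rng.uniform(0, 1, k))
            th = rng.uniform(0, 2 * np.pi, k)
            for ri, ti in zip(r, th):
                p = Point2D(par.x + ri * math.cos(ti), par.y + ri * math.sin(ti))
                if poly.contains(p):
                    locations.append(p)
    elif process == "regular":
        n_target = rng.poisson(expected)
        locations = []
        attempts = 0
        while len(locations) < n_target and attempts < 200 * max(n_target, 1):
            (cand,) = _uniform_in_polygon(poly, 1, rng)
            attempts += 1
            if all(cand.distance(q) >= inhibition for q in locations):
                locations.append(cand)
    else:
        raise ValueError(f"unknown point process {process!r}")
    weights = np.asarray(category_weights, dtype=float)
    if weights.shape != (8,) or np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
        raise ValueError("category_weights must be 8 non-negative values summing to 1")
    codes = rng.choice(np.arange(1, 9), size=len(locations), p=weights)
    return [
        ResourcePoint(id=f"{id_prefix}{i:04d}", location=loc, category=ResourceCategory(int(c)))
        for i, (loc, c) in enumerate(zip(locations, codes))
    ]


# ---------------------------------------------------------------------------
# census generation


def gen_census(config: SimConfig) -> list[CensusSite]:
    """Simulate a full census: polygons, resources, and dog observations.

    Dog abundance is drawn as a continuous Gamma density with mean
    exp(X beta) under the census truth, converted to a whole-dog count by
    rounding; the analysis-facing density is then count/area, so the stored
    pair is self-consistent (round-trip error < 1 dog by construction).
    """
    rng = np.random.default_rng(config.seed)
    truth = config.census_truth
    sites: list[CensusSite] = []
    labels = ["rural"] * config.n_rural + ["urban"] * config.n_urban
    lo, hi = config.area_range_ha
    spacing = 3.0 * math.sqrt(hi * 10_000.0)  # keep site footprints disjoint
    for i, settlement in enumerate(labels):
        area = rng.uniform(lo, hi)
        center = (spacing * (i % 10), spacing * (i // 10))
        poly = gen_polygon(area, rng, center=center)
        lam = config.resource_intensity[settlement] * math.exp(
            rng.normal(0.0, config.intensity_log_sd) - config.intensity_log_sd**2 / 2.0
        )
        resources = gen_resources(
            poly, lam, rng,
            process=config.point_process,
            category_weights=config.category_weights[settlement],
            cluster_radius=config.cluster_radius,
            offspring_mean=config.offspring_mean,
            inhibition=config.inhibition,
            id_prefix=f"s{i:03d}_r",
        )
        res_density = sum(p.score for p in resources) / area
        is_urban = 1.0 if settlement == "urban" else 0.0
        eta = (
            truth.intercept
            + truth.resource_slope * res_density
            + truth.urban * is_urban
            + truth.interaction * res_density * is_urban
        )
        mu = math.exp(eta)
        shape = 1.0 / truth.dispersion
        density = rng.gamma(shape, mu / shape)
        n_dogs = int(round(density * area))
        dogs = _gen_dog_records(n_dogs, config, rng)
        sites.append(
            CensusSite(
                id=f"site{i:03d}",
                polygon=poly,
                settlement=settlement,
                resource_points=resources,
                dog_records=dogs,
            )
        )
    return sites


def _gen_dog_records(n: int, config: SimConfig, rng: np.random.Generator) -> list[DogRecord]:
    ages = rng.choice(["adult", "juvenile", "pup"], size=n, p=config.age_class_probs)
    sexes = rng.choice(["F", "M"], size=n, p=[config.frac_female, 1 - config.frac_female])
    return [DogRecord(sex=s, age_class=a) for s, a in zip(sexes, ages)]


# ---------------------------------------------------------------------------
# territory panel generation


def gen_territory_panel(config: SimConfig) -> list[TerritoryRecord]:
    """Simulate the group x season territory panel.

    Per group: a random intercept, a spatial scale and a mean point count
    for its resource layouts (creating between-group spread in dispersion
    and richness), and a subset of available food categories (decorrelating
    heterogeneity from richness).  Per season: a fresh layout, an adult
    composition from the intercept-only truth with a size-independent sex
    ratio, and a territory area from the
    five-predictor Gamma truth plus group intercept and season effect, with
    a convex territory polygon of that area drawn around the layout
    centroid (shifted onto a resource point if it would otherwise contain
    none).
    """
    rng = np.random.default_rng(config.seed + 1)
    truth = config.territory_truth
    records: list[TerritoryRecord] = []
    for g in range(config.n_groups):
        b_g = rng.normal(0.0, truth.group_sd)
        mean_count = rng.uniform(*config.richness_mean_range)
        radius = rng.uniform(*config.layout_radius_range)
        k_cats = rng.integers(config.categories_range[0], config.categories_range[1] + 1)
        cats = rng.choice(np.arange(1, 9), size=k_cats, replace=False)
        for season in config.seasons:
            # composition is redrawn each season (membership churn around
            # mating; independent rows keep the intercept-only adult-count
            # truth testable without pseudoreplication).  The sex ratio is
            # drawn independently of group size: a binomial split would make
            # extreme ratios a small-group artefact and leak group size into
            # the ratio covariate.
            shape_a = 1.0 / truth.adults_dispersion
            mu_a = math.exp(truth.adults_intercept)
            n_adults = max(2, int(round(rng.gamma(shape_a, mu_a / shape_a))))
            target_ratio = rng.lognormal(0.0, 0.6)
            n_male = int(np.clip(round(n_adults * target_ratio / (1.0 + target_ratio)),
                                 0, n_adults - 1))
            n_female = n_adults - n_male
            mfr = n_male / n_female
            n_pts = 0
            while n_pts < 2:
                n_pts = rng.poisson(mean_count)
            r = radius * np.sqrt(rng.uniform(0, 1, n_pts))
            th = rng.uniform(0, 2 * np.pi, n_pts)
            pts = [
                ResourcePoint(
                    id=f"g{g:02d}_{season}_r{i:03d}",
                    location=Point2D(ri * math.cos(ti), ri * math.sin(ti)),
                    category=ResourceCategory(int(rng.choice(cats))),
                )
                for i, (ri, ti) in enumerate(zip(r, th))
            ]
            richness = len(pts)
            het = len({p.category for p in pts})
            locs = np.array([(p.location.x, p.location.y) for p in pts])
            diffs = locs[:, None, :] - locs[None, :, :]
            dmat = np.sqrt((diffs**2).sum(-1))
            disp = dmat.sum() / (richness * (richness - 1))

            n_pups = int(rng.poisson(config.pups_post_mating_mean)) if season == "post_mating" else 0

            c = truth.area_coefs
            eta = (
                c[0] + c[1] * n_adults + c[2] * het + c[3] * richness
                + c[4] * mfr + c[5] * disp
                + b_g + truth.season_effects[season]
            )
            shape_t = 1.0 / truth.area_dispersion
            area = rng.gamma(shape_t, math.exp(eta) / shape_t)
            centroid = locs.mean(axis=0)
            poly = gen_polygon(area, rng, center=(float(centroid[0]), float(centroid[1])))
            if not any(poly.contains(p.location) for p in pts):
                anchor = pts[int(rng.integers(len(pts)))].location
                dx = anchor.x - float(centroid[0])
                dy = anchor.y - float(centroid[1])
                poly = Polygon2D([Point2D(v.x + dx, v.y + dy) for v in poly.vertices])
            records.append(
                TerritoryRecord(
                    group_id=f"group{g:02d}",
                    season=season,
                    resource_points=pts,
                    n_male=n_male,
                    n_female=n_female,
                    n_pups=n_pups,
                    territory=poly,
                )
            )
    if config.panel_size is not None and config.panel_size < len(records):
        keep = rng.choice(len(records), size=config.panel_size, replace=False)
        records = [records[i] for i in sorted(keep)]
    return records


def gen_metric_panel(
    n_groups: int,
    seed: int,
    intercept: float = 1.5,
    season_effects: Optional[dict] = None,
    group_sd: float = 0.4,
    dispersion_by_season: Optional[dict] = None,
    response: str = "heterogeneity",
    seasons: Sequence[str] = SEASONS,
) -> pd.DataFrame:
    """Direct Gamma-GLMM draws of a territory metric, for calibration runs.

    Generates response values with mean exp(intercept + season effect +
    group intercept) and season-specific Gamma dispersion, bypassing the
    spatial layer — the instrument for type-I-error and power studies of
    the dispersion submodel.
    """
    rng = np.random.default_rng(seed)
    season_effects = season_effects or {s: 0.0 for s in seasons}
    dispersion_by_season = dispersion_by_season or {s: 0.1 for s in seasons}
    rows = []
    for g in range(n_groups):
        b_g = rng.normal(0.0, group_sd)
        for s in seasons:
            mu = math.exp(intercept + season_effects[s] + b_g)
            phi = dispersion_by_season[s]
            val = rng.gamma(1.0 / phi, mu * phi)
            rows.append({"group_id": f"g{g:02d}", "season": s, response: val})
    return pd.DataFrame(rows)
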