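"""File interchange: GeoJSON for geometries, CSV for tabular records.

Serialized coordinates are always WGS84 lon/lat; planar metre coordinates
are an in-memory representation only.  Each study site is planarized with a
local projection centred on its polygon centroid.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .geometry import Point2D, Polygon2D, Projection, project, unproject
from .metrics import TerritoryRecord, metrics_frame
from .scoring import CensusSite, DogRecord, ResourceCategory, ResourcePoint, category_table

PathLike = Union[str, Path]


def polygons_to_geojson(
    polys: Sequence[Polygon2D],
    projection: Projection,
    properties: Optional[Sequence[dict]] = None,
) -> dict:
    feats = []
    for i, poly in enumerate(polys):
        ring = unproject(list(poly.vertices), projection)
        ring.append(ring[0])
        feats.append(
            {
                "type": "Feature",
                "properties": (properties[i] if properties else {}),
                "geometry": {"type": "Polygon", "coordinates": [[list(c) for c in ring]]},
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def geojson_to_polygons(fc: dict, projection: Projection) -> list[tuple[Polygon2D, dict]]:
    out = []
    for feat in fc["features"]:
        geom = feat["geometry"]
        if geom["type"] != "Polygon":
            raise ValueError(f"expected Polygon features, got {geom['type']}")
        ring = [tuple(c) for c in geom["coordinates"][0]]
        if ring[0] == ring[-1]:
            ring = ring[:-1]
        pts = project(ring, projection)
        out.append((Polygon2D(pts), feat.get("properties", {})))
    return out


def write_census(sites: Sequence[CensusSite], out_dir: PathLike, projection: Projection) -> dict:
    """Write sites.geojson, resources.csv, dogs.csv, categories.csv.

    Returns a manifest dict of paths and row counts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fc = polygons_to_geojson(
        [s.polygon for s in sites], projection,
        [{"site_id": s.id, "settlement": s.settlement} for s in sites],
    )
    (out / "sites.geojson").write_text(json.dumps(fc, indent=1, sort_keys=True))

    res_rows, dog_rows = [], []
    for s in sites:
        for rp in s.resource_points:
            lon, lat = unproject([rp.location], projection)[0]
            res_rows.append(
                {"site_id": s.id, "lon": lon, "lat": lat, "category_code": int(rp.category)}
            )
        for d in s.dog_records:
            dog_rows.append(
                {"site_id": s.id, "time": "", "sex": d.sex, "age": d.age_class,
                 "group_size": d.group_size}
            )
    pd.DataFrame(res_rows, columns=["site_id", "lon", "lat", "category_code"]).to_csv(
        out / "resources.csv", index=False
    )
    pd.DataFrame(dog_rows, columns=["site_id", "time", "sex", "age", "group_size"]).to_csv(
        out / "dogs.csv", index=False
    )
    pd.DataFrame(category_table()).to_csv(out / "categories.csv", index=False)
    return {
        "sites_geojson": str(out / "sites.geojson"),
        "resources_csv": str(out / "resources.csv"),
        "dogs_csv": str(out / "dogs.csv"),
        "categories_csv": str(out / "categories.csv"),
        "n_sites": len(sites),
        "n_resources": len(res_rows),
        "n_dogs": len(dog_rows),
    }


def read_census(
    sites_geojson: PathLike,
    resources_csv: PathLike,
    dogs_csv: PathLike,
    projection: Projection,
) -> list[CensusSite]:
    fc = json.loads(Path(sites_geojson).read_text())
    polys = geojson_to_polygons(fc, projection)
    resources = pd.read_csv(resources_csv)
    dogs = pd.read_csv(dogs_csv)
    sites = []
    for poly, props in polys:
        sid = props["site_id"]
        rsub = resources[resources.site_id == sid]
        locs = project(list(zip(rsub.lon, rsub.lat)), projection)
        rpts = [
            ResourcePoint(id=f"{sid}_r{i:04d}", location=loc,
                          category=ResourceCategory(int(code)))
            for i, (loc, code) in enumerate(zip(locs, rsub.category_code))
        ]
        dsub = dogs[dogs.site_id == sid]
        drecs = [
            DogRecord(sex=row.sex, age_class=row.age, group_size=int(row.group_size))
            for row in dsub.itertuples()
        ]
        sites.append(
            CensusSite(id=sid, polygon=poly, settlement=props["settlement"],
                       resource_points=rpts, dog_records=drecs)
        )
    return sites


def write_territory_panel(records: Sequence[TerritoryRecord], out_path: PathLike) -> dict:
    """One CSV row per group x season with composition and computed metrics."""
    df = metrics_frame(records)
    Path(out_path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_path, index=False)
    return {"groups_csv": str(out_path), "n_rows": len(df)}


def read_territory_panel(path: PathLike) -> pd.DataFrame:
    """Load a group x season table with precomputed metrics."""
    df = pd.read_csv(path)
    required = {"group_id", "season", "territory_area"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"territory table missing columns: {sorted(missing)}")
    if "n_adults" not in df.columns and {"n_male", "n_female"} <= set(df.columns):
        df["n_adults"] = df["n_male"] + df["n_female"]
    if "mf_ratio" not in df.columns and {"n_male", "n_female"} <= set(df.columns):
        df["mf_ratio"] = df["n_male"] / df["n_female"].where(df["n_female"] > 0)
    return df
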