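"""Reading and writing regions, datasets and results.

Regions travel as GeoJSON FeatureCollections (one feature per SU carrying
``id`` and ``population`` properties, plus one feature with ``role:
"boundary"`` holding the outer polygon) or as a centroid CSV
(``su_id,x,y,population``) with a companion boundary-geometry GeoJSON file.
All tabular outputs are plain CSV with a header; coordinates must be planar —
files declaring a geographic (lon/lat) CRS are rejected, project them first.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, mapping, shape

from .geometry import EdgeCoefficients
from .region import Dataset, Region, SpatialUnit, validate_region
from .scan import ScanResult
from .type1 import ParticipationVector

__all__ = [
    "read_region",
    "write_region",
    "write_dataset_csv",
    "read_dataset_csv",
    "write_scan_results_csv",
    "write_participation_csv",
    "write_participation_geojson",
]


def _check_planar(obj: dict, path: Path) -> None:
    crs = obj.get("crs")
    if crs is None:
        return
    name = str(crs.get("properties", {}).get("name", "")).upper()
    if "4326" in name or "CRS84" in name:
        raise ValueError(
            f"{path}: coordinates are geographic (lon/lat, {name}); distances "
            "must be Euclidean — project to a planar CRS before loading"
        )


def _validated(region: Region, source: Path) -> Region:
    problems = validate_region(region)
    if problems:
        raise ValueError(f"{source}: invalid region: " + "; ".join(problems))
    return region


def read_region(path: str | Path, boundary_path: str | Path | None = None) -> Region:
    """Load a region from GeoJSON, or from a centroid CSV plus boundary GeoJSON.

    The format is chosen by extension: ``.geojson``/``.json`` for the
    FeatureCollection layout, ``.csv`` (requiring ``boundary_path``) for the
    tabular layout.  The loaded region is validated; violations raise with the
    offending unit named.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        if boundary_path is None:
            raise ValueError("CSV regions need a companion boundary geometry file")
        return _read_region_csv(path, Path(boundary_path))
    with open(path) as fh:
        obj = json.load(fh)
    _check_planar(obj, path)
    if obj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    units: list[SpatialUnit] = []
    boundary = None
    for k, feat in enumerate(obj.get("features", [])):
        props = feat.get("properties") or {}
        geom = feat.get("geometry")
        if geom is None:
            raise ValueError(f"{path}: feature {k} has no geometry")
        if props.get("role") == "boundary":
            boundary = shape(geom)
            continue
        if "id" not in props:
            raise ValueError(f"{path}: feature {k} lacks an 'id' property")
        if "population" not in props:
            raise ValueError(
                f"{path}: feature {k} (id {props['id']!r}) lacks a 'population' property"
            )
        g = shape(geom)
        if isinstance(g, Point):
            centroid, poly = (g.x, g.y), None
        else:
            c = g.centroid
            centroid, poly = (c.x, c.y), g
        if "centroid" in props:
            centroid = tuple(props["centroid"])
        units.append(
            SpatialUnit(
                id=str(props["id"]),
                centroid=centroid,
                population=float(props["population"]),
                polygon=poly,
            )
        )
    if boundary is None:
        raise ValueError(f"{path}: no feature with role 'boundary' found")
    return _validated(Region(units=units, boundary=boundary), path)


def _read_region_csv(path: Path, boundary_path: Path) -> Region:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"su_id", "x", "y", "population"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    with open(boundary_path) as fh:
        obj = json.load(fh)
    _check_planar(obj, boundary_path)
    geom = obj.get("geometry", obj)  # accept bare geometry or a Feature
    boundary = shape(geom)
    units = [
        SpatialUnit(
            id=str(r.su_id), centroid=(float(r.x), float(r.y)), population=float(r.population)
        )
        for r in df.itertuples()
    ]
    return _validated(Region(units=units, boundary=boundary), path)


def write_region(region: Region, path: str | Path, boundary_path: str | Path | None = None) -> None:
    """Write a region as GeoJSON, or as centroid CSV + boundary file for ``.csv``."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.DataFrame(
            {
                "su_id": region.ids,
                "x": region.centroids[:, 0],
                "y": region.centroids[:, 1],
                "population": region.populations,
            }
        )
        df.to_csv(path, index=False)
        if boundary_path is not None:
            with open(boundary_path, "w") as fh:
                json.dump(mapping(region.boundary), fh)
        return
    features = [
        {
            "type": "Feature",
            "geometry": mapping(
                u.polygon if u.polygon is not None else Point(u.centroid)
            ),
            "properties": {
                "id": u.id,
                "population": u.population,
                "centroid": list(u.centroid),
            },
        }
        for u in region.units
    ]
    features.append(
        {
            "type": "Feature",
            "geometry": mapping(region.boundary),
            "properties": {"role": "boundary"},
        }
    )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_dataset_csv(dataset: Dataset, path: str | Path) -> None:
    """One simulated dataset as the canonical 5-column-plus-id table."""
    r = dataset.region
    pd.DataFrame(
        {
            "su_id": r.ids,
            "x": r.centroids[:, 0],
            "y": r.centroids[:, 1],
            "population": r.populations,
            "observed": dataset.observed,
            "expected": dataset.expected,
        }
    ).to_csv(Path(path), index=False)


def read_dataset_csv(path: str | Path, region: Region, lambda_: float) -> Dataset:
    df = pd.read_csv(path)
    order = df.set_index("su_id").loc[region.ids]
    return Dataset(region=region, lambda_=lambda_, observed=order["observed"].to_numpy())


def write_scan_results_csv(results: Sequence[ScanResult], path: str | Path) -> None:
    pd.DataFrame(
        {
            "dataset_id": np.arange(len(results)),
            "center_id": [r.mlc.center_id for r in results],
            "member_ids": [";".join(r.mlc.member_ids) for r in results],
            "llr": [r.llr for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    ).to_csv(Path(path), index=False)


def write_participation_csv(
    p: ParticipationVector, eps: EdgeCoefficients, region: Region, path: str | Path
) -> None:
    pd.DataFrame(
        {"su_id": region.ids, "P_i": p.p, "epsilon_i": eps.epsilon}
    ).to_csv(Path(path), index=False)


def write_participation_geojson(
    p: ParticipationVector, eps: EdgeCoefficients, region: Region, path: str | Path
) -> None:
    """Participation map as GeoJSON point features for external choropleths."""
    features = [
        {
            "type": "Feature",
            "geometry": mapping(
                u.polygon if u.polygon is not None else Point(u.centroid)
            ),
            "properties": {
                "id": u.id,
                "population": u.population,
                "P_i": float(p.p[i]),
                "epsilon_i": float(eps.epsilon[i]),
            },
        }
        for i, u in enumerate(region.units)
    ]
    with open(Path(path), "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
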