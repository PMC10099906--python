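"""Regional preferred-habitat area change.

The Southern Ocean is partitioned into five sectors (Atlantic, Central
Indian, East Indian, West Pacific, East Pacific, after the MEASO
assessment areas); preferred-habitat area is summed per region with
latitude-dependent geodesic cell areas, and percent change between the
current and each projected future mask is reported per climate
representation and scenario, with quartile summaries across the
ensemble.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from shapely import contains_xy
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.geometry import box

from .sphere import EARTH_RADIUS_KM

__all__ = ["RegionSet", "default_measo_sectors", "assign_regions",
           "cell_area", "percent_area_change", "summarize_ensemble"]

MEASO_REGION_NAMES = ("Atlantic", "Central Indian", "East Indian",
                      "West Pacific", "East Pacific")


@dataclass
class RegionSet:
    """Named, mutually non-overlapping lon/lat polygons."""

    regions: dict[str, BaseGeometry]

    def __post_init__(self) -> None:
        names = list(self.regions)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                inter = self.regions[a].intersection(self.regions[b])
                if inter.area > 1e-9:
                    raise ValueError(f"regions {a!r} and {b!r} overlap")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.regions)

    def to_geojson(self, path) -> None:
        features = [{"type": "Feature", "properties": {"name": name},
                     "geometry": mapping(geom)}
                    for name, geom in self.regions.items()]
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    @classmethod
    def from_geojson(cls, path) -> "RegionSet":
        with open(path) as fh:
            gj = json.load(fh)
        return cls({f["properties"]["name"]: shape(f["geometry"])
                    for f in gj["features"]})


def default_measo_sectors(lat_min: float = -90.0,
                          lat_max: float = -30.0) -> RegionSet:
    """Five meridional sectors approximating the MEASO assessment areas.

    Boundary meridians: Atlantic 70W-30E, Central Indian 30E-80E, East
    Indian 80E-150E, West Pacific 150E-130W (split at the antimeridian),
    East Pacific 130W-70W.  These are the package's own simplification of
    the authoritative polygons, which can be supplied as GeoJSON instead.
    """
    def sector(w, e):
        if w < e:
            return box(w, lat_min, e, lat_max)
        return box(w, lat_min, 180.0, lat_max).union(
            box(-180.0, lat_min, e, lat_max))

    return RegionSet({
        "Atlantic": sector(-70.0, 30.0),
        "Central Indian": sector(30.0, 80.0),
        "East Indian": sector(80.0, 150.0),
        "West Pacific": sector(150.0, -130.0),
        "East Pacific": sector(-130.0, -70.0),
    })


def assign_regions(lons: np.ndarray, lats: np.ndarray,
                   regions: RegionSet) -> xr.DataArray:
    """Label each grid cell by the region containing its centre; cells
    outside every polygon stay unlabelled (empty string)."""
    lon2, lat2 = np.meshgrid(np.asarray(lons, float), np.asarray(lats, float))
    labels = np.full(lon2.shape, "", dtype=object)
    for name, geom in regions.regions.items():
        inside = contains_xy(geom, lon2.ravel(), lat2.ravel()).reshape(lon2.shape)
        labels[inside & (labels == "")] = name
    return xr.DataArray(labels, coords={"lat": lats, "lon": lons},
                        dims=("lat", "lon"))


def cell_area(lat, resolution: float = 1.0):
    """Geodesic area (km^2) of a ``resolution``-degree cell centred at
    ``lat``: R^2 * d_lambda * (sin(lat + d_phi/2) - sin(lat - d_phi/2))."""
    lat = np.asarray(lat, dtype=float)
    half = np.radians(resolution / 2.0)
    dlon = np.radians(resolution)
    latr = np.radians(lat)
    return EARTH_RADIUS_KM ** 2 * dlon * (np.sin(latr + half) - np.sin(latr - half))


def _region_area(mask: np.ndarray, labels: np.ndarray,
                 areas: np.ndarray, name: str) -> float:
    return float(areas[mask & (labels == name)].sum())


def percent_area_change(current_mask: xr.DataArray, future_mask: xr.DataArray,
                        labels: xr.DataArray, taxon: str = "",
                        representation: str = "", scenario: str = "",
                        cell_areas: xr.DataArray | None = None,
                        ) -> pd.DataFrame:
    """Per-region current/future preferred area (km^2) and percent change
    100 * (future - current) / current.

    Regions with zero current area get NaN percent change, flagged.  Pass
    ``cell_areas`` of ones for a cell-count sensitivity mode.
    """
    if current_mask.shape != future_mask.shape or current_mask.shape != labels.shape:
        raise ValueError("masks and labels must share the grid")
    if cell_areas is None:
        lats = current_mask["lat"].to_numpy().astype(float)
        areas = np.broadcast_to(cell_area(lats)[:, None], current_mask.shape)
    else:
        areas = cell_areas.to_numpy()
    cur = current_mask.to_numpy().astype(bool)
    fut = future_mask.to_numpy().astype(bool)
    lab = labels.to_numpy()
    rows = []
    for name in pd.unique(lab[lab != ""].ravel()):
        a_cur = _region_area(cur, lab, areas, name)
        a_fut = _region_area(fut, lab, areas, name)
        rows.append({
            "taxon": taxon, "region": name, "representation": representation,
            "scenario": scenario, "current_km2": a_cur, "future_km2": a_fut,
            "pct_change": 100.0 * (a_fut - a_cur) / a_cur if a_cur > 0 else np.nan,
            "zero_current": a_cur == 0,
        })
    return pd.DataFrame(rows)


def summarize_ensemble(records: pd.DataFrame) -> pd.DataFrame:
    """Quartile summary of percent change across representations per
    (taxon, region, scenario): median, 25th/75th percentiles (linear,
    'type 7' interpolation), min and max."""
    def q(s, p):
        return float(np.percentile(s.to_numpy(float), p))

    out = (records.groupby(["taxon", "region", "scenario"], sort=True)
           ["pct_change"]
           .agg(n="size",
                median=lambda s: q(s, 50), q25=lambda s: q(s, 25),
                q75=lambda s: q(s, 75),
                min="min", max="max")
           .reset_index())
    return out
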