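"""Spatiotemporal alignment of gridded rasters to regions.

Heterogeneous environmental rasters (different grids, cadences) are reduced
to one value per region per calendar month:

1. ``zonal_mean`` — spatial reduction: the unweighted mean of raster values
   at pixels whose *centers* fall inside the region polygon.
2. ``to_monthly`` — temporal reduction: calendar-month means of the native
   observations, on a common monthly index.
3. ``static_average`` — collapse a monthly series to a single static value
   (used for land-cover fractions).

Regional series are carried as tidy DataFrames with columns
``(region_id, variable, month, value)``; missing values are NaN and always
propagate explicitly (never silently zero).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import xarray as xr
from shapely.geometry import mapping, shape

log = logging.getLogger("geohealth")

REGIONAL_COLUMNS = ["region_id", "variable", "month", "value"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class RegionSet:
    """Polygonal regions with a two-tier hierarchy and rook adjacency.

    ``table`` has columns ``region_id, level, parent_id, geometry`` (shapely
    polygons in the planar km CRS unless ``crs`` says otherwise).
    ``adjacency`` maps each region_id to a sorted list of neighbor ids;
    the relation is symmetric and irreflexive.
    """

    table: pd.DataFrame
    adjacency: dict[str, list[str]] = field(default_factory=dict)
    crs: str = "planar_km"

    @property
    def region_ids(self) -> list[str]:
        return list(self.table["region_id"])

    def geometry(self, region_id: str):
        row = self.table.loc[self.table["region_id"] == region_id]
        if row.empty:
            raise KeyError(f"unknown region {region_id!r}")
        return row["geometry"].iloc[0]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class RasterSeries:
    """A gridded variable over time on a fixed axis-aligned grid.

    ``values`` has shape (T, ny, nx); pixel (i, j) covers the square with
    lower-left corner ``(x0 + j*pixel_size, y0 + i*pixel_size)`` so its
    center is at ``(x0 + (j+0.5)*pixel_size, y0 + (i+0.5)*pixel_size)``.
    Missing pixels are NaN.
    """

    variable: str
    x0: float
    y0: float
    pixel_size: float
    times: pd.DatetimeIndex
    values: np.ndarray
    crs: str = "planar_km"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = pd.DatetimeIndex(self.times)
        if self.values.ndim != 3:
            raise ValueError("values must have shape (T, ny, nx)")
        if len(self.times) != self.values.shape[0]:
            raise ValueError("times length must match values.shape[0]")
        if len(self.times) > 1 and not self.times.is_monotonic_increasing:
            raise ValueError("timestamps must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1], self.values.shape[2]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinates as 2-D arrays of shape (ny, nx)."""
        ny, nx = self.shape
        xs = self.x0 + (np.arange(nx) + 0.5) * self.pixel_size
        ys = self.y0 + (np.arange(ny) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)


# ---------------------------------------------------------------------------
# Point-to-region assignment
# ---------------------------------------------------------------------------

def assign_points_to_regions(
    x: np.ndarray, y: np.ndarray, regions: RegionSet
) -> np.ndarray:
    """Assign each point to the region whose polygon covers it.

    Points on a shared boundary go to the region with the lexicographically
    smaller id (deterministic tie-break); points outside every polygon get
    the empty string.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    pts = shapely.points(x, y)
    geoms = np.asarray(regions.table["geometry"].to_numpy())
    ids = np.asarray(regions.table["region_id"], dtype=object)
    tree = shapely.STRtree(geoms)
    pt_idx, geom_idx = tree.query(pts, predicate="covered_by")
    out = np.full(len(pts), "", dtype=object)
    order = np.lexsort((ids[geom_idx], pt_idx))
    seen: set[int] = set()
    for k in order:
        p = int(pt_idx[k])
        if p not in seen:  # first hit per point is the lexicographic min
            seen.add(p)
            out[p] = ids[geom_idx[k]]
    return out


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def zonal_mean(raster: RasterSeries, regions: RegionSet) -> pd.DataFrame:
    """Per-region, per-timestamp unweighted mean over contained pixel centers.

    A pixel contributes to the region that covers its center; missing (NaN)
    pixels are excluded from the mean. A region containing no pixel centers
    gets NaN for every timestamp and a logged warning.

    Returns a tidy frame ``(region_id, variable, month, value)``.
    """
    if raster.crs != regions.crs:
        raise ValueError(
            f"CRS mismatch: raster {raster.crs!r} vs regions {regions.crs!r}"
        )
    cx, cy = raster.pixel_centers()
    assignment = assign_points_to_regions(cx.ravel(), cy.ravel(), regions)

    T = raster.values.shape[0]
    flat = raster.values.reshape(T, -1)
    rows: list[pd.DataFrame] = []
    for rid in regions.region_ids:
        mask = assignment == rid
        if not mask.any():
            log.warning(
                "region %s contains no pixel centers of %r; recorded as missing",
                rid, raster.variable,
            )
            vals = np.full(T, np.nan)
        else:
            with np.errstate(invalid="ignore"):
                vals = np.nanmean(flat[:, mask], axis=1)
        rows.append(pd.DataFrame({
            "region_id": rid,
            "variable": raster.variable,
            "month": raster.times,
            "value": vals,
        }))
    return pd.concat(rows, ignore_index=True)


def to_monthly(series: pd.DataFrame) -> pd.DataFrame:
    """Downsample a regional series to calendar-month means.

    The monthly value for a (region, variable) is the mean of the native
    observations whose timestamps fall in that calendar month (UTC calendar
    months, no proration). Months with no observations are absent from the
    output. An empty input yields an empty output.
    """
    if series.empty:
        return pd.DataFrame(columns=REGIONAL_COLUMNS)
    df = series.copy()
    df["month"] = pd.to_datetime(df["month"]).dt.to_period("M").dt.to_timestamp()
    out = (
        df.groupby(["region_id", "variable", "month"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    return out[REGIONAL_COLUMNS]


def static_average(series: pd.DataFrame) -> pd.DataFrame:
    """Collapse each (region, variable) monthly series to one static mean.

    The mean skips missing months; a series that is entirely missing stays
    missing and is flagged in the log. Returns ``(region_id, variable, value)``.
    """
    out = (
        series.groupby(["region_id", "variable"], sort=True)["value"]
        .mean()  # pandas mean skips NaN
        .reset_index()
    )
    all_missing = out["value"].isna()
    if all_missing.any():
        for _, r in out[all_missing].iterrows():
            log.warning(
                "static_average: %s/%s has no non-missing values",
                r["region_id"], r["variable"],
            )
    return out


# ---------------------------------------------------------------------------
# IO: GeoJSON regions, NetCDF rasters, CSV regional series
# ---------------------------------------------------------------------------

def write_regions_geojson(regions: RegionSet, path) -> None:
    features = []
    for _, row in regions.table.iterrows():
        features.append({
            "type": "Feature",
            "properties": {
                "region_id": row["region_id"],
                "level": row["level"],
                "parent_id": row["parent_id"],
                "neighbors": regions.adjacency.get(row["region_id"], []),
            },
            "geometry": mapping(row["geometry"]),
        })
    doc = {"type": "FeatureCollection", "crs_tag": regions.crs, "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True)


def read_regions_geojson(path) -> RegionSet:
    with open(path) as fh:
        doc = json.load(fh)
    rows, adjacency = [], {}
    for feat in doc["features"]:
        props = feat["properties"]
        rows.append({
            "region_id": props["region_id"],
            "level": props["level"],
            "parent_id": props["parent_id"],
            "geometry": shape(feat["geometry"]),
        })
        adjacency[props["region_id"]] = list(props.get("neighbors", []))
    table = pd.DataFrame(rows, columns=["region_id", "level", "parent_id", "geometry"])
    return RegionSet(table=table, adjacency=adjacency, crs=doc.get("crs_tag", "planar_km"))


def write_raster_netcdf(raster: RasterSeries, path) -> None:
    ny, nx = raster.shape
    ds = xr.Dataset(
        {raster.variable: (("time", "y", "x"), raster.values)},
        coords={
            "time": raster.times,
            "y": raster.y0 + (np.arange(ny) + 0.5) * raster.pixel_size,
            "x": raster.x0 + (np.arange(nx) + 0.5) * raster.pixel_size,
        },
        attrs={"crs_tag": raster.crs, "pixel_size": raster.pixel_size,
               "x0": raster.x0, "y0": raster.y0},
    )
    ds.to_netcdf(path, engine="scipy")


def read_raster_netcdf(path) -> RasterSeries:
    with xr.open_dataset(path, engine="scipy") as ds:
        name = [v for v in ds.data_vars][0]
        return RasterSeries(
            variable=name,
            x0=float(ds.attrs["x0"]),
            y0=float(ds.attrs["y0"]),
            pixel_size=float(ds.attrs["pixel_size"]),
            times=pd.DatetimeIndex(ds["time"].values),
            values=ds[name].values.copy(),
            crs=str(ds.attrs.get("crs_tag", "planar_km")),
        )


def write_regional_series(series: pd.DataFrame, path) -> None:
    series.to_csv(path, index=False)


def read_regional_series(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["month"])
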