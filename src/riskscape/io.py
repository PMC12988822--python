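"""File formats: track/dive CSV, raster stacks as NetCDF, land GeoJSON,
truth-parameter JSON sidecars, and run manifests.

CSV is the canonical tabular interchange; raster stacks are NetCDF via
xarray with day/year coordinates.  Readers validate schemas and reject
malformed rows with named-column errors.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import mapping, shape

from .raster import CovariateStack, RasterField

__all__ = ["read_tracks", "write_tracks", "read_dives", "write_dives",
           "write_raster_stack", "read_raster_stack", "write_land_geojson",
           "read_land_geojson", "write_truth_json", "SchemaError"]

TRACK_COLUMNS = {"animal_id", "datetime", "lc", "x", "y"}
DIVE_COLUMNS = {"animal_id", "datetime", "duration_s", "max_depth",
                "d1", "d2", "d3", "d4", "d5", "p1", "p2", "p3", "p4", "p5"}


class SchemaError(ValueError):
    pass


def _check_schema(df: pd.DataFrame, required: set, what: str) -> None:
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{what}: missing column(s) {sorted(missing)}")


def _parse_utc(series: pd.Series, what: str) -> pd.Series:
    """ISO-8601 with or without zone, normalised to naive UTC."""
    try:
        t = pd.to_datetime(series, utc=True, format="ISO8601")
    except (ValueError, TypeError) as e:
        bad = next((f"line {i + 2}: {v!r}" for i, v in enumerate(series)
                    if pd.isna(pd.to_datetime(v, errors="coerce", utc=True))), "")
        raise SchemaError(f"{what}: unparseable datetime ({bad})") from e
    return t.dt.tz_localize(None)


def read_tracks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, TRACK_COLUMNS, "tracks")
    df["datetime"] = _parse_utc(df["datetime"], "tracks")
    bad = ~np.isfinite(df[["x", "y"]].to_numpy(float)).all(axis=1)
    if bad.any():
        raise SchemaError(f"tracks: non-finite coordinates at line(s) "
                          f"{[i + 2 for i in np.flatnonzero(bad)[:5]]}")
    return df.sort_values(["animal_id", "datetime"]).reset_index(drop=True)


def write_tracks(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["datetime"] = pd.to_datetime(out["datetime"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_dives(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_schema(df, DIVE_COLUMNS, "dives")
    df["datetime"] = _parse_utc(df["datetime"], "dives")
    shallow = df["max_depth"] <= 2.0
    if shallow.any():
        df = df.loc[~shallow]
    return df.sort_values(["animal_id", "datetime"]).reset_index(drop=True)


def write_dives(df: pd.DataFrame, path) -> None:
    out = df[[c for c in df.columns if c in DIVE_COLUMNS | {"x", "y"}]].copy()
    out["datetime"] = pd.to_datetime(out["datetime"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def write_raster_stack(stack: CovariateStack, path) -> None:
    geo = stack.geometry
    coords = {"y": geo.node_y(), "x": geo.node_x()}
    days = sorted(stack.ice)
    ds = xr.Dataset(
        {
            "bathymetry": (("y", "x"), stack.bathymetry.values),
            "dist_coast": (("y", "x"), stack.dist_coast.values),
            "land": (("y", "x"), stack.land.astype(np.int8)),
            "ice": (("day", "y", "x"),
                    np.stack([stack.ice[d].values for d in days])),
        },
        coords={**coords, "day": days},
        attrs={"time_origin": str(stack.time_origin), "cell_size": geo.cell_size},
    )
    if stack.risk:
        rdays = sorted(stack.risk)
        ds["risk"] = (("rday", "y", "x"),
                      np.stack([stack.risk[d].values for d in rdays]))
        ds = ds.assign_coords(rday=rdays)
    if stack.prey_diversity:
        years = sorted(stack.prey_diversity)
        f0 = stack.prey_diversity[years[0]]
        ds["prey_diversity"] = (("year", "py", "px"),
                                np.stack([stack.prey_diversity[y].values for y in years]))
        ds = ds.assign_coords(year=years, py=f0.node_y(), px=f0.node_x())
        ds.attrs["prey_cell_size"] = f0.cell_size
    ds.to_netcdf(path)


def read_raster_stack(path) -> CovariateStack:
    ds = xr.load_dataset(path)
    cs = float(ds.attrs["cell_size"])
    x0 = float(ds["x"][0])
    y0 = float(ds["y"][0])

    def fld(arr, stamp="static", name=""):
        return RasterField(np.asarray(arr), x0, y0, cs, stamp=stamp, name=name)

    stack = CovariateStack(
        bathymetry=fld(ds["bathymetry"], name="bathymetry"),
        dist_coast=fld(ds["dist_coast"], name="dist_coast"),
        land=np.asarray(ds["land"]).astype(bool),
        time_origin=np.datetime64(ds.attrs["time_origin"]),
    )
    for d in np.asarray(ds["day"]):
        stack.ice[int(d)] = fld(ds["ice"].sel(day=d), stamp=int(d), name="ice")
    if "risk" in ds:
        for d in np.asarray(ds["rday"]):
            stack.risk[int(d)] = fld(ds["risk"].sel(rday=d), stamp=int(d), name="risk")
    if "prey_diversity" in ds:
        pcs = float(ds.attrs["prey_cell_size"])
        px0, py0 = float(ds["px"][0]), float(ds["py"][0])
        for yv in np.asarray(ds["year"]):
            stack.prey_diversity[int(yv)] = RasterField(
                np.asarray(ds["prey_diversity"].sel(year=yv)), px0, py0, pcs,
                stamp=int(yv), name="prey_diversity")
    return stack


def write_land_geojson(polygon, path) -> None:
    Path(path).write_text(json.dumps({
        "type": "Feature", "properties": {"layer": "land"},
        "geometry": mapping(polygon)}))


def read_land_geojson(path):
    return shape(json.loads(Path(path).read_text())["geometry"])


def write_truth_json(truth, path) -> None:
    d = truth.to_dict() if hasattr(truth, "to_dict") else asdict(truth)
    Path(path).write_text(json.dumps(d, indent=2, default=float))
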