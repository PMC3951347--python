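"""Readers and writers for the package's plain-text interchange formats.

Vector data travel as GeoJSON (regions, lakes, core polygons, points) and
CSV (points with ``x,y,class`` columns); rasters as ESRI ASCII grids
(``.asc``, one file per layer, NODATA tagged), which every GIS reads.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .point_pattern import PointPattern
from .raster import NODATA, Grid, RasterStack
from .region import StudyRegion

__all__ = [
    "write_region_geojson", "read_region_geojson",
    "write_points_csv", "read_points_csv",
    "write_points_geojson",
    "write_ascii_grid", "read_ascii_grid",
    "write_raster_stack", "read_raster_stack",
    "write_core_geojson",
]


# --- vector -----------------------------------------------------------------

def write_region_geojson(region: StudyRegion, path: str | Path) -> None:
    feat = {
        "type": "Feature",
        "properties": {"role": "study_region", "area_m2": region.area},
        "geometry": mapping(region.polygon),
    }
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": [feat]}))


def read_region_geojson(path: str | Path) -> StudyRegion:
    gj = json.loads(Path(path).read_text())
    if gj.get("type") == "FeatureCollection":
        geom = shape(gj["features"][0]["geometry"])
    elif gj.get("type") == "Feature":
        geom = shape(gj["geometry"])
    else:
        geom = shape(gj)
    if geom.geom_type == "MultiPolygon":  # take the largest part
        geom = max(geom.geoms, key=lambda g: g.area)
    boundary = np.asarray(geom.exterior.coords)[:-1]
    lakes = [np.asarray(r.coords)[:-1] for r in geom.interiors]
    return StudyRegion(boundary=boundary, inner_lakes=lakes)


def write_points_csv(pattern: PointPattern, path: str | Path) -> None:
    pd.DataFrame(
        {"x": pattern.points[:, 0], "y": pattern.points[:, 1], "class": pattern.labels}
    ).to_csv(path, index=False)


def read_points_csv(path: str | Path, region: StudyRegion) -> PointPattern:
    """Parse an ``x,y,class`` table; malformed rows raise with file + line."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse point CSV: {exc}") from exc
    for col in ("x", "y"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2  # header + 1-based
            raise ValueError(f"{path}:{line}: non-numeric value in column {col!r}")
        df[col] = coerced
    labels = df["class"].astype(str).to_numpy() if "class" in df.columns else np.full(
        len(df), "generic", dtype=object
    )
    return PointPattern(df[["x", "y"]].to_numpy(float), labels, region)


def write_points_geojson(pattern: PointPattern, path: str | Path) -> None:
    feats = [
        {
            "type": "Feature",
            "properties": {"class": str(lab)},
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
        }
        for (x, y), lab in zip(pattern.points, pattern.labels)
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def write_core_geojson(polygons: list, path: str | Path, properties: dict | None = None) -> None:
    feats = [
        {"type": "Feature", "properties": dict(properties or {}), "geometry": mapping(poly)}
        for poly in polygons
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


# --- raster -----------------------------------------------------------------

def write_ascii_grid(grid: Grid, values: np.ndarray, path: str | Path) -> None:
    """ESRI ASCII grid with corner registration and the NODATA tag set."""
    nrows, ncols = values.shape
    yll = grid.origin[1] - nrows * grid.cell_size
    header = (
        f"ncols {ncols}\nnrows {nrows}\nxllcorner {grid.origin[0]:.6f}\n"
        f"yllcorner {yll:.6f}\ncellsize {grid.cell_size:.6f}\nNODATA_value {NODATA:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, values, fmt="%.6g")


def read_ascii_grid(path: str | Path) -> tuple[Grid, np.ndarray]:
    with open(path) as fh:
        head = {}
        for _ in range(6):
            key, val = fh.readline().split()
            head[key.lower()] = float(val)
        values = np.loadtxt(fh)
    ncols, nrows = int(head["ncols"]), int(head["nrows"])
    cell = head["cellsize"]
    origin = (head["xllcorner"], head["yllcorner"] + nrows * cell)
    grid = Grid(origin=origin, cell_size=cell, nrows=nrows, ncols=ncols)
    values = values.reshape(nrows, ncols)
    return grid, values


def write_raster_stack(stack: RasterStack, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, layer in stack.layers.items():
        write_ascii_grid(stack.grid, layer, out / f"{name}.asc")


def read_raster_stack(in_dir: str | Path, region: StudyRegion) -> RasterStack:
    in_dir = Path(in_dir)
    paths = sorted(in_dir.glob("*.asc"))
    if not paths:
        raise ValueError(f"{in_dir}: no .asc raster layers found")
    grid = None
    layers = {}
    for p in paths:
        g, vals = read_ascii_grid(p)
        if grid is None:
            grid = g
        elif g != grid:
            raise ValueError(f"{p}: raster grid does not match the other layers")
        layers[p.stem] = vals
    mask = np.all([v != NODATA for v in layers.values()], axis=0)
    return RasterStack(grid=grid, layers=layers, mask=mask, region=region)
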