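"""File I/O: single-band rasters (TIFF / ESRI ASCII grid), GeoJSON perimeters.

Rasters are written either as single-band TIFF (byte for binary burn maps
with nodata 255, float32 for fraction maps) with a small JSON sidecar
(``<file>.aux.json``) carrying the grid geometry, or as ESRI ASCII grid
(``.asc``), a plain-text raster format whose header carries the geometry
itself.  Fire perimeters are read from and written to GeoJSON; geometries
must already be in a projected equal-area CRS (no reprojection is done).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import tifffile
from shapely.geometry import MultiPolygon, Polygon, mapping, shape

from .errors import GeometryError
from .grid import BurnGrid, FireEvent, FractionGrid, GridSpec

__all__ = [
    "write_burn_grid",
    "read_burn_grid",
    "write_fraction_grid",
    "read_fraction_grid",
    "read_fire_events",
    "write_fire_events",
]

BURN_NODATA = 255


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".aux.json")


def _write_sidecar(path: Path, spec: GridSpec, year: int | None, kind: str) -> None:
    meta = {
        "kind": kind,
        "origin_x": spec.origin_x,
        "origin_y": spec.origin_y,
        "pixel_size": spec.pixel_size,
        "n_rows": spec.n_rows,
        "n_cols": spec.n_cols,
        "crs_label": spec.crs_label,
        "year": year,
        "nodata": BURN_NODATA if kind == "burn" else None,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing grid-geometry sidecar {sidecar} for raster {path}"
        )
    return json.loads(sidecar.read_text())


def _spec_from_meta(meta: dict) -> GridSpec:
    return GridSpec(
        meta["origin_x"],
        meta["origin_y"],
        meta["pixel_size"],
        meta["n_rows"],
        meta["n_cols"],
        meta.get("crs_label", ""),
    )


def _write_asc(path: Path, spec: GridSpec, values: np.ndarray, nodata: float) -> None:
    xll = spec.origin_x
    yll = spec.origin_y - spec.n_rows * spec.pixel_size
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {xll!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {spec.pixel_size!r}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, values, fmt="%.10g")


def _read_asc(path: Path) -> tuple[GridSpec, np.ndarray]:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    cell = header["cellsize"]
    spec = GridSpec(
        header["xllcorner"],
        header["yllcorner"] + n_rows * cell,
        cell,
        n_rows,
        n_cols,
    )
    return spec, np.atleast_2d(values)


def write_burn_grid(grid: BurnGrid, path: str | Path) -> None:
    """Write a binary burn map as .tif (byte, nodata 255) or .asc text raster."""
    path = Path(path)
    if path.suffix.lower() == ".asc":
        _write_asc(path, grid.spec, grid.values, BURN_NODATA)
    else:
        tifffile.imwrite(path, grid.values.astype(np.uint8))
    _write_sidecar(path, grid.spec, grid.year, "burn")


def read_burn_grid(path: str | Path) -> BurnGrid:
    path = Path(path)
    meta = _read_sidecar(path)
    if path.suffix.lower() == ".asc":
        spec, values = _read_asc(path)
        spec = _spec_from_meta(meta)  # sidecar keeps crs_label
    else:
        values = tifffile.imread(path)
        spec = _spec_from_meta(meta)
    return BurnGrid(spec, values.astype(np.uint8), year=meta.get("year"))


def write_fraction_grid(grid: FractionGrid, path: str | Path) -> None:
    """Write a burned-fraction map as .tif (float32) or .asc text raster."""
    path = Path(path)
    if path.suffix.lower() == ".asc":
        _write_asc(path, grid.spec, grid.values, -9999.0)
    else:
        tifffile.imwrite(path, grid.values.astype(np.float32))
    meta_path = _sidecar_path(path)
    _write_sidecar(path, grid.spec, None, "fraction")
    meta = json.loads(meta_path.read_text())
    meta["factor"] = grid.factor
    meta_path.write_text(json.dumps(meta, indent=1))


def read_fraction_grid(path: str | Path) -> FractionGrid:
    path = Path(path)
    meta = _read_sidecar(path)
    if path.suffix.lower() == ".asc":
        _, values = _read_asc(path)
    else:
        values = tifffile.imread(path)
    spec = _spec_from_meta(meta)
    return FractionGrid(spec, np.asarray(values, dtype=np.float64), meta.get("factor", 1))


def read_fire_events(path: str | Path) -> list[FireEvent]:
    """Read fire perimeters from a GeoJSON FeatureCollection.

    Required feature properties: a fire id (``id`` or ``fire_id``) and
    ``year``; ``area_ha`` is taken from the properties when present, else
    computed from the polygon area (m^2 / 10^4).
    """
    data = json.loads(Path(path).read_text())
    events = []
    for feat in data.get("features", []):
        geom = shape(feat["geometry"])
        if not isinstance(geom, (Polygon, MultiPolygon)):
            raise GeometryError(
                f"unsupported geometry type {geom.geom_type}; expected (Multi)Polygon"
            )
        props = feat.get("properties", {}) or {}
        fid = str(props.get("id", props.get("fire_id", feat.get("id", ""))))
        year = int(props["year"])
        area_ha = float(props.get("area_ha") or geom.area / 1e4)
        events.append(FireEvent(id=fid, year=year, polygon=geom, area_ha=area_ha))
    return events


def write_fire_events(events: Iterable[FireEvent], path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(ev.polygon),
            "properties": {
                "id": ev.id,
                "year": ev.year,
                "area_ha": ev.area_ha,
                "category": ev.category,
            },
        }
        for ev in events
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )
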