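"""Equal-area raster geometry, polygon rasterization, and binary burn-map algebra.

All maps in an assessment share one projected equal-area grid.  Burned-area
maps are binary rasters (0 = Not Burned, 1 = Burned); degrading them to a
coarser resolution produces rasters of burned-area *fraction* per pixel,
which is where mixed-pixel (Pareto) analysis starts.

Conventions
-----------
* The grid origin is the upper-left corner; pixel ``(row, col)`` spans the
  half-open box ``[x0 + col*s, x0 + (col+1)*s) x (y0 - (row+1)*s, y0 - row*s]``
  with row 0 at the top, matching common geospatial raster practice.
* Rasterization uses the maximum-area rule: a pixel is labelled Burned iff
  the burned fraction of its footprint is >= 0.5.  An exact 50/50 split is
  labelled Burned (deterministic tie-break, documented in the methods note).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import MultiPolygon, Polygon, box
from shapely.validation import explain_validity

from .errors import GeometryError, GridMismatchError

__all__ = [
    "GridSpec",
    "BurnGrid",
    "FractionGrid",
    "FireEvent",
    "FIRE_SIZE_CLASSES",
    "categorize_area",
    "rasterize_polygons",
    "union_grids",
    "aggregate_fraction",
    "burned_area_ha",
]

#: Fire-size classes (lower bound inclusive, upper bound exclusive), in ha.
FIRE_SIZE_CLASSES: tuple[tuple[str, float, float], ...] = (
    ("very_small", 0.0, 100.0),
    ("small", 100.0, 1_000.0),
    ("medium", 1_000.0, 10_000.0),
    ("large", 10_000.0, 100_000.0),
    ("very_large", 100_000.0, float("inf")),
)

CATEGORY_NAMES = tuple(name for name, _, _ in FIRE_SIZE_CLASSES)

# Tolerance absorbing float noise in exact polygon-pixel intersection areas
# so that a true 50% split reliably maps to Burned.
_TIE_EPS = 1e-9


def categorize_area(area_ha: float) -> str:
    """Assign a fire size class by half-open [lower, upper) area intervals."""
    if not area_ha > 0:
        raise ValueError(f"fire area must be positive, got {area_ha}")
    for name, lo, hi in FIRE_SIZE_CLASSES:
        if lo <= area_ha < hi:
            return name
    raise AssertionError("unreachable")  # pragma: no cover


@dataclass(frozen=True)
class GridSpec:
    """Geometry of an equal-area raster grid.

    Parameters
    ----------
    origin_x, origin_y
        Projected coordinates (m) of the upper-left corner of the grid.
    pixel_size
        Side of the square pixels in metres (> 0).
    n_rows, n_cols
        Raster dimensions (>= 1).
    crs_label
        Free-text description of the projected CRS; metadata only.
    """

    origin_x: float
    origin_y: float
    pixel_size: float
    n_rows: int
    n_cols: int
    crs_label: str = ""

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def pixel_area_ha(self) -> float:
        """Pixel area in hectares (pixel_size^2 / 10_000)."""
        return self.pixel_size**2 / 10_000.0

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid in map units."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.pixel_size,
            self.origin_x + self.n_cols * self.pixel_size,
            self.origin_y,
        )

    def pixel_box(self, row: int, col: int) -> Polygon:
        """Shapely box of one pixel footprint."""
        s = self.pixel_size
        x0 = self.origin_x + col * s
        y1 = self.origin_y - row * s
        return box(x0, y1 - s, x0 + s, y1)

    def coarsen(self, factor: int) -> "GridSpec":
        """Spec of the grid aggregated by an integer ``factor`` (dims must divide)."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        if self.n_rows % factor or self.n_cols % factor:
            raise ValueError(
                f"dimensions {self.shape} not divisible by factor {factor}"
            )
        return GridSpec(
            self.origin_x,
            self.origin_y,
            self.pixel_size * factor,
            self.n_rows // factor,
            self.n_cols // factor,
            self.crs_label,
        )


def _check_same_spec(a: GridSpec, b: GridSpec) -> None:
    if a != b:
        raise GridMismatchError(f"grid specs differ: {a} vs {b}")


@dataclass
class BurnGrid:
    """Binary burned / non-burned raster for one year."""

    spec: GridSpec
    values: np.ndarray
    year: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.spec.shape}"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("burn grid values must be 0 or 1")
        self.values = self.values.astype(np.uint8)

    @property
    def burned_pixels(self) -> int:
        return int(self.values.sum())

    def burned_area_ha(self) -> float:
        return burned_area_ha(self)


@dataclass
class FractionGrid:
    """Coarse raster of burned-area fraction per pixel, from block aggregation.

    ``padded_mask`` flags coarse pixels whose footprint includes zero-padding
    added to reach divisible dimensions; those pixels should be excluded from
    Pareto statistics.
    """

    spec: GridSpec
    values: np.ndarray
    factor: int
    padded_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.spec.shape}"
            )
        if self.factor < 1:
            raise ValueError("factor must be >= 1")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("fractions must lie in [0, 1]")

    def burned_area_ha(self) -> float:
        """Total burned area implied by the fractions (conserved from the fine map)."""
        return float(self.values.sum()) * self.spec.pixel_area_ha


@dataclass
class FireEvent:
    """One reference fire: perimeter polygon plus bookkeeping attributes."""

    id: str
    year: int
    polygon: Polygon | MultiPolygon
    area_ha: float
    category: str = field(default="")

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise ValueError(f"fire {self.id}: area_ha must be positive")
        expected = categorize_area(self.area_ha)
        if not self.category:
            self.category = expected
        elif self.category != expected:
            raise ValueError(
                f"fire {self.id}: category {self.category!r} inconsistent with "
                f"area {self.area_ha} ha (expected {expected!r})"
            )


def _validate_geometry(geom: Polygon | MultiPolygon, label: str) -> None:
    if not geom.is_valid:
        raise GeometryError(f"invalid geometry for {label}: {explain_validity(geom)}")


def rasterize_polygons(
    events: Iterable[FireEvent], spec: GridSpec, year: int | None = None
) -> BurnGrid:
    """Rasterize fire perimeters with the maximum-area rule.

    A pixel is labelled Burned iff >= 50% of its footprint is covered by the
    union of the fire polygons (exact polygon-pixel intersection areas; ties
    at 50% go to Burned).  Polygons entirely outside the grid contribute
    nothing and raise a warning.

    Raises
    ------
    GeometryError
        For self-intersecting or otherwise invalid rings.
    """
    events = list(events)
    frac = np.zeros(spec.shape, dtype=np.float64)
    s = spec.pixel_size
    px_area = s * s
    xmin, ymin, xmax, ymax = spec.bounds

    for ev in events:
        _validate_geometry(ev.polygon, f"fire {ev.id}")
        gxmin, gymin, gxmax, gymax = ev.polygon.bounds
        if gxmax <= xmin or gxmin >= xmax or gymax <= ymin or gymin >= ymax:
            warnings.warn(
                f"fire {ev.id} lies entirely outside the grid; skipped",
                stacklevel=2,
            )
            continue
        c0 = max(0, int(np.floor((gxmin - spec.origin_x) / s)))
        c1 = min(spec.n_cols - 1, int(np.floor((gxmax - spec.origin_x) / s)))
        r0 = max(0, int(np.floor((spec.origin_y - gymax) / s)))
        r1 = min(spec.n_rows - 1, int(np.floor((spec.origin_y - gymin) / s)))
        for row in range(r0, r1 + 1):
            for col in range(c0, c1 + 1):
                cell = spec.pixel_box(row, col)
                inter = ev.polygon.intersection(cell)
                if not inter.is_empty:
                    frac[row, col] += inter.area / px_area

    # Overlapping fires within one year can push the summed fraction past 1.
    np.clip(frac, 0.0, 1.0, out=frac)
    values = (frac >= 0.5 - _TIE_EPS).astype(np.uint8)
    if year is None:
        years = {ev.year for ev in events}
        year = years.pop() if len(years) == 1 else None
    return BurnGrid(spec, values, year=year)


def union_grids(grids: Sequence[BurnGrid]) -> BurnGrid:
    """Logical union (any-burned) of binary grids sharing one spec."""
    grids = list(grids)
    if not grids:
        raise ValueError("need at least one grid")
    spec = grids[0].spec
    years = set()
    for g in grids:
        _check_same_spec(spec, g.spec)
        if g.year is not None:
            years.add(g.year)
    if len(years) > 1:
        raise ValueError(f"cannot union grids from different years: {sorted(years)}")
    values = np.logical_or.reduce([g.values.astype(bool) for g in grids])
    return BurnGrid(spec, values.astype(np.uint8), year=years.pop() if years else None)


def aggregate_fraction(fine: BurnGrid, factor: int, pad: bool = False) -> FractionGrid:
    """Degrade a binary map to a coarser grid of burned-area fractions.

    Each coarse pixel's value is the mean of its ``factor x factor`` block of
    fine pixels, so the total burned area is conserved.  By default the fine
    dimensions must be multiples of ``factor``; with ``pad=True`` the map is
    padded with Not Burned pixels and the affected coarse pixels are flagged
    in ``padded_mask``.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    vals = fine.values
    n_rows, n_cols = vals.shape
    padded_mask = None
    if n_rows % factor or n_cols % factor:
        if not pad:
            raise ValueError(
                f"dimensions {vals.shape} not divisible by factor {factor}; "
                "pass pad=True to zero-pad"
            )
        pr = (-n_rows) % factor
        pc = (-n_cols) % factor
        vals = np.pad(vals, ((0, pr), (0, pc)))
        n_rows, n_cols = vals.shape
        padded_mask = np.zeros((n_rows // factor, n_cols // factor), dtype=bool)
        if pr:
            padded_mask[-1, :] = True
        if pc:
            padded_mask[:, -1] = True
    coarse_spec = GridSpec(
        fine.spec.origin_x,
        fine.spec.origin_y,
        fine.spec.pixel_size * factor,
        n_rows // factor,
        n_cols // factor,
        fine.spec.crs_label,
    )
    blocks = vals.reshape(
        coarse_spec.n_rows, factor, coarse_spec.n_cols, factor
    ).astype(np.float64)
    fractions = blocks.mean(axis=(1, 3))
    return FractionGrid(coarse_spec, fractions, factor, padded_mask=padded_mask)


def burned_area_ha(grid: BurnGrid) -> float:
    """Burned area in hectares: count of Burned pixels times the pixel area.

    For the canonical 50 m reference grid each pixel represents 0.25 ha.
    """
    return grid.burned_pixels * grid.spec.pixel_area_ha
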