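"""Spatial units, regular grids, and zonal aggregation.

Every indicator module shares the same two primitives: a regular,
axis-aligned raster grid and a set of polygonal analysis units
(regions and countries).  Rasterization uses a binary cell-center
containment rule; zonal statistics ignore nodata cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

from .errors import DataIntegrityError, EmptyMaskError, UndefinedMeanError

__all__ = [
    "RasterGrid",
    "SpatialUnit",
    "rasterize_unit",
    "zonal_mean",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_units",
    "write_units",
]

UNIT_LEVELS = ("region", "country")


@dataclass
class RasterGrid:
    """Rectangular grid of values with an origin at the top-left outer corner.

    Parameters
    ----------
    values
        2-D float array, row 0 at the top (northernmost row).
    cell_size
        Edge length of one square cell, in CRS units.
    origin
        ``(x, y)`` of the outer corner of cell ``(0, 0)``: the minimum x and
        the *maximum* y of the grid extent.
    nodata
        Sentinel for missing cells.
    semantics
        Free-text tag describing what the values mean.
    """

    values: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999.0
    semantics: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise DataIntegrityError("grid must be a non-empty 2-D array")
        if self.cell_size <= 0:
            raise DataIntegrityError("cell_size must be positive")
        valid = self.values[~self.nodata_mask()]
        if not np.all(np.isfinite(valid)):
            raise DataIntegrityError("non-nodata grid values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def nodata_mask(self) -> np.ndarray:
        return self.values == self.nodata

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(x, y)`` center coordinate arrays, each shaped like values."""
        rows, cols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(cols) + 0.5) * self.cell_size
        ys = y0 - (np.arange(rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def extent_polygon(self) -> BaseGeometry:
        rows, cols = self.shape
        x0, y0 = self.origin
        return shapely.box(x0, y0 - rows * self.cell_size, x0 + cols * self.cell_size, y0)

    def copy_with(self, values: np.ndarray, semantics: str | None = None) -> "RasterGrid":
        return RasterGrid(
            values=np.asarray(values, dtype=float),
            cell_size=self.cell_size,
            origin=self.origin,
            nodata=self.nodata,
            semantics=self.semantics if semantics is None else semantics,
        )


@dataclass
class SpatialUnit:
    """One analysis unit (a region or one of its component countries)."""

    id: str
    name: str
    level: str
    geometry: BaseGeometry
    parent_region: str | None = None

    def __post_init__(self) -> None:
        if self.level not in UNIT_LEVELS:
            raise DataIntegrityError(f"unit level must be one of {UNIT_LEVELS}, got {self.level!r}")
        if not self.geometry.is_valid:
            self.geometry = make_valid(self.geometry)


def rasterize_unit(unit: SpatialUnit, template: RasterGrid) -> np.ndarray:
    """Boolean mask of template cells whose *center* lies inside the unit.

    Raises
    ------
    EmptyMaskError
        If no cell center falls inside the unit geometry.
    """
    xs, ys = template.cell_centers()
    mask = shapely.contains_xy(unit.geometry, xs.ravel(), ys.ravel()).reshape(template.shape)
    if not mask.any():
        raise EmptyMaskError(f"unit {unit.id!r} contains no cell center of the template grid")
    return mask


def zonal_mean(grid: RasterGrid, mask: np.ndarray) -> float:
    """Arithmetic mean of masked, non-nodata cells.

    Nodata cells are excluded from both numerator and denominator.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise DataIntegrityError("mask shape does not match grid shape")
    valid = mask & ~grid.nodata_mask()
    if not valid.any():
        raise UndefinedMeanError("all masked cells are nodata; zonal mean undefined")
    return float(grid.values[valid].mean())


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (plain text, lossless float round-trip via repr format)
# ---------------------------------------------------------------------------

def write_ascii_grid(grid: RasterGrid, path: str) -> None:
    rows, cols = grid.shape
    x0, y0 = grid.origin
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner {x0!r}\n"
        f"yllcorner {(y0 - rows * grid.cell_size)!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str, semantics: str = "") -> RasterGrid:
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    rows = int(header["nrows"])
    cols = int(header["ncols"])
    if values.shape != (rows, cols):
        raise DataIntegrityError(f"{path}: body shape {values.shape} != header ({rows}, {cols})")
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + rows * cell)
    return RasterGrid(values, cell, origin, nodata=header["nodata_value"], semantics=semantics)


# ---------------------------------------------------------------------------
# Units GeoJSON I/O
# ---------------------------------------------------------------------------

def write_units(units: Iterable[SpatialUnit], path: str) -> None:
    features = []
    for u in units:
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "id": u.id,
                    "name": u.name,
                    "level": u.level,
                    "parent_region": u.parent_region,
                },
                "geometry": mapping(u.geometry),
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_units(path: str) -> list[SpatialUnit]:
    with open(path) as fh:
        fc = json.load(fh)
    units = []
    seen: set[str] = set()
    for feat in fc["features"]:
        props = feat["properties"]
        if props["id"] in seen:
            raise DataIntegrityError(f"duplicate unit id {props['id']!r}")
        seen.add(props["id"])
        units.append(
            SpatialUnit(
                id=props["id"],
                name=props.get("name", props["id"]),
                level=props["level"],
                geometry=shape(feat["geometry"]),
                parent_region=props.get("parent_region"),
            )
        )
    return units
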