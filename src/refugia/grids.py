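"""Planar regular grids and lightweight raster containers.

The study system is a planar world: "latitude" and "longitude" are realised as
northing and easting in metres.  Coarse cells default to 10 km squares
(hectads, the recording unit of British plant atlases); elevation and
land-cover grids live on a finer subdivision of the same lattice.

Rasters are stored with row 0 at the *bottom* (cell ``(col=0, row=0)`` is the
lower-left cell) and written to disk as ESRI ASCII grids — a plain-text raster
format readable by GDAL, ``terra`` and ``raster``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

__all__ = ["GridSpec", "Raster", "read_ascii_grid", "write_ascii_grid"]

_NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular axis-aligned grid.

    Cells are half-open: cell ``(col, row)`` covers
    ``[origin_x + col*s, origin_x + (col+1)*s) x [origin_y + row*s, ...)``
    with ``s = cell_size``; cell (0, 0) sits at the lower-left corner.

    Parameters
    ----------
    cell_size : float
        Edge length of a coarse cell in metres (default 10 km, a hectad).
    fine_factor : int
        Integer subdivision used for the elevation / land-cover grids.
    """

    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 10_000.0
    n_cols: int = 60
    n_rows: int = 60
    fine_factor: int = 10

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell per axis")
        if int(self.fine_factor) != self.fine_factor or self.fine_factor < 1:
            raise ValueError("fine_factor must be an integer >= 1")

    # -- extent ------------------------------------------------------------
    @property
    def width(self) -> float:
        return self.n_cols * self.cell_size

    @property
    def height(self) -> float:
        return self.n_rows * self.cell_size

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of the gridded domain."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.width,
            self.origin_y + self.height,
        )

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(n_rows, n_cols)``."""
        return (self.n_rows, self.n_cols)

    def fine(self) -> "GridSpec":
        """The fine grid (DEM / land-cover lattice) sharing this origin."""
        return GridSpec(
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_size=self.cell_size / self.fine_factor,
            n_cols=self.n_cols * self.fine_factor,
            n_rows=self.n_rows * self.fine_factor,
            fine_factor=1,
        )

    # -- cell geometry -----------------------------------------------------
    def cell_bounds(self, col, row):
        """Bounds (minx, miny, maxx, maxy) of one or more cells."""
        col = np.asarray(col)
        row = np.asarray(row)
        s = self.cell_size
        return (
            self.origin_x + col * s,
            self.origin_y + row * s,
            self.origin_x + (col + 1) * s,
            self.origin_y + (row + 1) * s,
        )

    def cell_box(self, col: int, row: int):
        return box(*self.cell_bounds(col, row))

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Centre coordinates: (x of each column, y of each row)."""
        s = self.cell_size
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * s
        ys = self.origin_y + (np.arange(self.n_rows) + 0.5) * s
        return xs, ys

    def cells_in_bbox(self, minx, miny, maxx, maxy):
        """Index ranges of cells whose footprint overlaps an open bbox.

        Returns ``(col0, col1, row0, row1)`` inclusive, or ``None`` when the
        bbox misses the grid entirely.  Zero-width contact along a shared
        boundary does not count (half-open cells).
        """
        s = self.cell_size
        col0 = int(np.floor((minx - self.origin_x) / s))
        col1 = int(np.ceil((maxx - self.origin_x) / s)) - 1
        row0 = int(np.floor((miny - self.origin_y) / s))
        row1 = int(np.ceil((maxy - self.origin_y) / s)) - 1
        col0, row0 = max(col0, 0), max(row0, 0)
        col1, row1 = min(col1, self.n_cols - 1), min(row1, self.n_rows - 1)
        if col0 > col1 or row0 > row1:
            return None
        return col0, col1, row0, row1

    def cells_intersecting(self, geom: BaseGeometry) -> tuple[np.ndarray, np.ndarray]:
        """Cells whose footprint has positive-area intersection with ``geom``.

        Returns ``(cols, rows)`` index arrays (possibly empty).  Touching a
        cell only along its boundary does not count.
        """
        rng = self.cells_in_bbox(*geom.bounds)
        if rng is None:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        col0, col1, row0, row1 = rng
        cols, rows = np.meshgrid(
            np.arange(col0, col1 + 1), np.arange(row0, row1 + 1)
        )
        cols, rows = cols.ravel(), rows.ravel()
        minx, miny, maxx, maxy = self.cell_bounds(cols, rows)
        boxes = shapely.box(minx, miny, maxx, maxy)
        areas = shapely.area(shapely.intersection(boxes, geom))
        keep = areas > 0.0
        return cols[keep], rows[keep]


@dataclass
class Raster:
    """A single-band raster: a 2-D array on a :class:`GridSpec`.

    ``values[row, col]`` with row 0 at the bottom.  ``NaN`` marks missing.
    """

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"raster shape {self.values.shape} does not match grid "
                f"{self.grid.shape}"
            )

    def at_cells(self, cols: np.ndarray, rows: np.ndarray) -> np.ndarray:
        return self.values[np.asarray(rows), np.asarray(cols)]

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(values=values, grid=self.grid)


def write_ascii_grid(raster: Raster, path: str | Path, fmt: str = "%.6g") -> None:
    """Write a raster as an ESRI ASCII grid (rows top-down on disk)."""
    g = raster.grid
    vals = np.flipud(np.asarray(raster.values, dtype=float))
    vals = np.where(np.isnan(vals), _NODATA, vals)
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.origin_x!r}\n"
        f"yllcorner {g.origin_y!r}\n"
        f"cellsize {g.cell_size!r}\n"
        f"NODATA_value {_NODATA:g}"
    )
    np.savetxt(path, vals, fmt=fmt, header=header, comments="")


def read_ascii_grid(path: str | Path, fine_factor: int = 1) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)
    nodata = header.get("nodata_value", _NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    grid = GridSpec(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        n_cols=int(header["ncols"]),
        n_rows=int(header["nrows"]),
        fine_factor=fine_factor,
    )
    return Raster(values=np.flipud(vals), grid=grid)
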