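"""Planar raster grids in projected-km coordinates.

All geometry in this package lives in a projected planar system with
kilometre units: spatial correlation scales are quoted in km and distances
are Euclidean.  Rasters are cell-center registered, stored row-major from
the top-left, with half-open cell intervals [x0, x0+dx) horizontally and
(ytop-dy*(r+1), ytop-dy*r] resolved by flooring (a point exactly on the top
edge belongs to row 0; a point on the bottom edge is outside).

Raster I/O uses the ESRI ASCII grid format (plain text), which any GIS
stack can read and write.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "GridGeometry",
    "Raster",
    "extract_at_points",
    "regrid_bilinear",
    "read_ascii_grid",
    "write_ascii_grid",
]


@dataclass(frozen=True)
class GridGeometry:
    """Regular grid: ``x0, ytop`` is the outer corner of the top-left cell."""

    x0: float
    ytop: float
    dx: float
    dy: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell sizes must be positive")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one cell per axis")

    @property
    def x1(self) -> float:
        return self.x0 + self.nx * self.dx

    @property
    def ybottom(self) -> float:
        return self.ytop - self.ny * self.dy

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x of each column, y of each row), both 1-D."""
        xs = self.x0 + (np.arange(self.nx) + 0.5) * self.dx
        ys = self.ytop - (np.arange(self.ny) + 0.5) * self.dy
        return xs, ys

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (x, y) coordinates of every cell center, row-major."""
        xs, ys = self.cell_centers()
        xx, yy = np.meshgrid(xs, ys)
        return xx.ravel(), yy.ravel()

    def locate(self, x, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col, inside-mask).

        Rows/cols for outside points are clipped into range; use the mask.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.dx).astype(int)
        row = np.floor((self.ytop - y) / self.dy).astype(int)
        # a point exactly on the top edge: (ytop - y)/dy == 0 -> row 0, inside
        inside = (col >= 0) & (col < self.nx) & (row >= 0) & (row < self.ny)
        return (
            np.clip(row, 0, self.ny - 1),
            np.clip(col, 0, self.nx - 1),
            inside,
        )


@dataclass
class Raster:
    """A single gridded layer: float values on a :class:`GridGeometry`.

    Missing cells are NaN.
    """

    geometry: GridGeometry
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"{self.geometry.shape}"
            )

    @classmethod
    def constant(cls, geometry: GridGeometry, value: float) -> "Raster":
        return cls(geometry, np.full(geometry.shape, float(value)))

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(self.geometry, values)


def extract_at_points(raster: Raster, x, y) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-cell (containing-cell) lookup of raster values at points.

    Returns ``(values, inside_mask)``; values for points outside the raster
    extent are NaN and flagged False in the mask rather than dropped.
    Raises ``ValueError`` if *every* point falls outside the extent.
    """
    row, col, inside = raster.geometry.locate(x, y)
    if not np.any(inside):
        raise ValueError("all points fall outside the raster extent")
    out = raster.values[row, col].astype(float)
    out[~inside] = np.nan
    return out, inside


def regrid_bilinear(raster: Raster, target: GridGeometry) -> Raster:
    """Bilinear interpolation of a raster onto a finer (or equal) grid.

    Interpolates between source cell centers; target centers beyond the
    outermost source centers (but within the source extent) are clamped to
    the edge value, so output never overshoots the source min/max.
    """
    src = raster.geometry
    if target.dx > src.dx + 1e-12 or target.dy > src.dy + 1e-12:
        raise ValueError("target resolution must be finer than or equal to source")
    if (
        target.x0 >= src.x1
        or target.x1 <= src.x0
        or target.ytop <= src.ybottom
        or target.ybottom >= src.ytop
    ):
        raise ValueError("target extent does not overlap the source raster")

    xs, ys = src.cell_centers()
    # RegularGridInterpolator wants strictly increasing axes; rows run top-down
    interp = RegularGridInterpolator(
        (ys[::-1], xs), raster.values[::-1, :], method="linear", bounds_error=False
    )
    tx, ty = target.center_mesh()
    tx = np.clip(tx, xs[0], xs[-1])
    ty = np.clip(ty, ys[-1], ys[0])
    vals = interp(np.column_stack([ty, tx])).reshape(target.shape)
    return Raster(target, vals)


def write_ascii_grid(path, raster: Raster, nodata: float = -9999.0) -> None:
    """Write an ESRI ASCII grid (requires square cells)."""
    g = raster.geometry
    if abs(g.dx - g.dy) > 1e-9:
        raise ValueError("ASCII grid requires square cells (dx == dy)")
    vals = np.where(np.isfinite(raster.values), raster.values, nodata)
    header = (
        f"ncols {g.nx}\n"
        f"nrows {g.ny}\n"
        f"xllcorner {g.x0!r}\n"
        f"yllcorner {g.ybottom!r}\n"
        f"cellsize {g.dx!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid` (or a GIS)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    nx, ny = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    geom = GridGeometry(
        x0=header["xllcorner"],
        ytop=header["yllcorner"] + ny * cell,
        dx=cell,
        dy=cell,
        nx=nx,
        ny=ny,
    )
    vals = np.atleast_2d(np.asarray(vals, dtype=float)).reshape(ny, nx)
    nodata = header.get("nodata_value")
    if nodata is not None:
        vals = np.where(vals == nodata, np.nan, vals)
    return Raster(geom, vals)
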