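"""Raster grid container and plain-text (ESRI ASCII) raster IO.

A :class:`RasterGrid` is a rectangular array of cell values on a regular
square grid. Nodata cells are stored as NaN. The georeference is minimal:
cell size in metres, the (x, y) coordinate of the *outer corner* of the
top-left cell, and a free-text CRS tag that is carried through every
operation but never interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid", "extract_points"]


@dataclass
class RasterGrid:
    """A single-band raster on a regular square grid.

    Parameters
    ----------
    values
        2-D float array; NaN marks nodata.
    cell_size
        Edge length of a cell in metres (> 0).
    origin
        (x, y) of the outer corner of the top-left cell; y decreases
        downwards through the rows (north-up convention).
    crs_tag
        Free-text coordinate-reference label, e.g. ``"EPSG:31468"``.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def x_centers(self) -> np.ndarray:
        """x coordinate of each column's cell centres."""
        x0 = self.origin[0]
        return x0 + (np.arange(self.ncols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        """y coordinate of each row's cell centres (decreasing)."""
        y0 = self.origin[1]
        return y0 - (np.arange(self.nrows) + 0.5) * self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin[0] + (col + 0.5) * self.cell_size,
            self.origin[1] - (row + 0.5) * self.cell_size,
        )

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/column of the cell containing (x, y)."""
        col = int(np.floor((x - self.origin[0]) / self.cell_size))
        row = int(np.floor((self.origin[1] - y) / self.cell_size))
        return row, col

    def like(self, values: np.ndarray) -> "RasterGrid":
        """New raster with the same georeference and the given values."""
        return replace(self, values=np.asarray(values, dtype=float))

    def aligned_with(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )


def read_ascii_grid(path, crs_tag: str = "") -> RasterGrid:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            pos = fh.tell()
            parts = fh.readline().split()
            # header lines start with a keyword; data lines with a number
            if len(parts) == 2 and parts[0][:1].isalpha():
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    ncols = int(header.get("ncols", data.shape[1]))
    nrows = int(header.get("nrows", data.shape[0]))
    if data.shape != (nrows, ncols):
        data = data.reshape(nrows, ncols)
    cell = float(header.get("cellsize", 1.0))
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    if "xllcorner" in header:
        x0 = header["xllcorner"]
        y0 = header["yllcorner"] + nrows * cell
    elif "xllcenter" in header:
        x0 = header["xllcenter"] - cell / 2
        y0 = header["yllcenter"] - cell / 2 + nrows * cell
    else:
        x0, y0 = 0.0, nrows * cell
    return RasterGrid(data, cell, (x0, y0), crs_tag)


def write_ascii_grid(raster: RasterGrid, path, nodata: float = -9999.0) -> None:
    """Write an ESRI ASCII grid (.asc). The CRS tag goes into a sidecar .prj-txt."""
    vals = np.where(np.isfinite(raster.values), raster.values, nodata)
    x0 = raster.origin[0]
    yll = raster.origin[1] - raster.nrows * raster.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {x0:.6f}\n")
        fh.write(f"yllcorner {yll:.6f}\n")
        fh.write(f"cellsize {raster.cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        np.savetxt(fh, vals, fmt="%.6f")
    if raster.crs_tag:
        with open(str(path) + ".crs.txt", "w") as fh:
            fh.write(raster.crs_tag + "\n")


def extract_points(raster: RasterGrid, x, y, method: str = "bilinear") -> np.ndarray:
    """Sample raster values at point coordinates.

    ``bilinear`` interpolates between the four surrounding cell centres
    (falling back to the containing cell where a neighbour is nodata or the
    point lies in the outer half-cell rim); ``nearest`` takes the containing
    cell.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    out = np.full(x.shape, np.nan)
    cs = raster.cell_size
    xc0 = raster.origin[0] + 0.5 * cs
    yc0 = raster.origin[1] - 0.5 * cs
    for i in range(x.size):
        fcol = (x[i] - xc0) / cs
        frow = (yc0 - y[i]) / cs
        r0, c0 = int(np.floor(frow)), int(np.floor(fcol))
        if method == "bilinear" and 0 <= r0 < raster.nrows - 1 and 0 <= c0 < raster.ncols - 1:
            q = raster.values[r0 : r0 + 2, c0 : c0 + 2]
            if np.all(np.isfinite(q)):
                tr = frow - r0
                tc = fcol - c0
                out[i] = (
                    q[0, 0] * (1 - tr) * (1 - tc)
                    + q[0, 1] * (1 - tr) * tc
                    + q[1, 0] * tr * (1 - tc)
                    + q[1, 1] * tr * tc
                )
                continue
        row, col = raster.index_of(x[i], y[i])
        if 0 <= row < raster.nrows and 0 <= col < raster.ncols:
            out[i] = raster.values[row, col]
    return out
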