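"""Planar raster grids with plain-text (ESRI ASCII) persistence.

All rasters in the package live on north-up, square-celled grids in one
planar metric coordinate frame. Row 0 is the northern edge; ``y`` decreases
with increasing row index.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import shapely

NODATA = -9999.0


@dataclass
class RasterGrid:
    """A single-band raster: array + georeferencing.

    Parameters
    ----------
    data : ndarray (nrows, ncols)
        Cell values, row 0 at the top (north).
    x_origin, y_origin : float
        Coordinates of the grid's north-west corner (outer edge).
    cell_size : float
        Square cell edge length in metres.
    nodata : float
        Sentinel for missing cells.
    """

    data: np.ndarray
    x_origin: float = 0.0
    y_origin: float = 0.0
    cell_size: float = 5.0
    nodata: float = NODATA

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer grid edges."""
        nrows, ncols = self.data.shape
        return (
            self.x_origin,
            self.y_origin - nrows * self.cell_size,
            self.x_origin + ncols * self.cell_size,
            self.y_origin,
        )

    def copy(self, data: np.ndarray | None = None) -> "RasterGrid":
        return replace(self, data=self.data.copy() if data is None else data)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Coordinate arrays (xs of columns, ys of rows) of cell centres."""
        nrows, ncols = self.data.shape
        xs = self.x_origin + (np.arange(ncols) + 0.5) * self.cell_size
        ys = self.y_origin - (np.arange(nrows) + 0.5) * self.cell_size
        return xs, ys

    def xy_to_rowcol(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        col = np.floor((np.asarray(x) - self.x_origin) / self.cell_size).astype(int)
        row = np.floor((self.y_origin - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def rowcol_to_xy(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        x = self.x_origin + (np.asarray(col) + 0.5) * self.cell_size
        y = self.y_origin - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def inside(self, row, col) -> np.ndarray:
        nrows, ncols = self.data.shape
        return (np.asarray(row) >= 0) & (np.asarray(row) < nrows) & (
            np.asarray(col) >= 0
        ) & (np.asarray(col) < ncols)

    def sample(self, x, y):
        """Nearest-cell values at coordinates; error if outside the grid."""
        row, col = self.xy_to_rowcol(x, y)
        if not np.all(self.inside(row, col)):
            raise ValueError("sample coordinates fall outside the grid")
        return self.data[row, col]

    # --- plain-text persistence (ESRI ASCII grid) -------------------------

    def write_ascii(self, path) -> None:
        nrows, ncols = self.data.shape
        yll = self.y_origin - nrows * self.cell_size
        header = (
            f"ncols {ncols}\n"
            f"nrows {nrows}\n"
            f"xllcorner {self.x_origin!r}\n"
            f"yllcorner {yll!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {self.nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.data, fmt="%.10g")

    @classmethod
    def read_ascii(cls, path) -> "RasterGrid":
        meta = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            data = np.loadtxt(fh)
        data = np.atleast_2d(data)
        cell = meta["cellsize"]
        return cls(
            data=data,
            x_origin=meta["xllcorner"],
            y_origin=meta["yllcorner"] + meta["nrows"] * cell,
            cell_size=cell,
            nodata=meta.get("nodata_value", NODATA),
        )


def template_like(grid: RasterGrid, fill: float | None = None) -> RasterGrid:
    data = np.full(grid.shape, grid.nodata if fill is None else fill, dtype=float)
    return RasterGrid(data, grid.x_origin, grid.y_origin, grid.cell_size, grid.nodata)


def rasterize_features(features, template: RasterGrid, *, line_buffer: float | None = None) -> RasterGrid:
    """Burn (geometry, value) pairs into a copy of ``template``.

    Cell-centre-in-polygon assignment: a cell takes the value iff its centre
    intersects the geometry. Lines (and points) are buffered by half a cell
    (``line_buffer`` overrides) before the centre test, so a linear feature
    claims the cells whose centres its half-cell corridor covers. Later
    features overwrite earlier ones.
    """
    out = template_like(template)
    xs, ys = template.cell_centers()
    xx, yy = np.meshgrid(xs, ys)
    half = template.cell_size / 2.0 if line_buffer is None else line_buffer
    for geom, value in features:
        g = geom
        if g.geom_type in ("LineString", "MultiLineString", "Point", "MultiPoint"):
            g = g.buffer(half)
        mask = shapely.intersects_xy(g, xx.ravel(), yy.ravel()).reshape(xx.shape)
        out.data[mask] = value
    return out


def resample_nearest(src: RasterGrid, template: RasterGrid) -> RasterGrid:
    """Nearest-neighbour resample of ``src`` onto the template's grid."""
    xs, ys = template.cell_centers()
    xx, yy = np.meshgrid(xs, ys)
    row, col = src.xy_to_rowcol(xx, yy)
    nrows, ncols = src.shape
    row = np.clip(row, 0, nrows - 1)
    col = np.clip(col, 0, ncols - 1)
    out = template_like(template)
    out.data[:, :] = src.data[row, col]
    out.nodata = src.nodata
    return out


def cells_on_geometry(grid: RasterGrid, geom, step_frac: float = 0.25):
    """(row, col) index arrays of cells touched by a line geometry.

    The line is densified at ``step_frac`` of a cell and each sample point is
    mapped to its cell; this is exact for lines that are not grazing corners.
    """
    step = grid.cell_size * step_frac
    parts = getattr(geom, "geoms", [geom])
    pts = []
    for part in parts:
        n = max(int(np.ceil(part.length / step)), 1)
        d = np.linspace(0.0, part.length, n + 1)
        pts.append(np.asarray([part.interpolate(t).coords[0] for t in d]))
    pts = np.vstack(pts)
    row, col = grid.xy_to_rowcol(pts[:, 0], pts[:, 1])
    keep = grid.inside(row, col)
    rc = np.unique(np.stack([row[keep], col[keep]], axis=1), axis=0)
    return rc[:, 0], rc[:, 1]
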