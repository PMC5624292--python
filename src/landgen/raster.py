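"""Georeferenced land-use rasters on geographic (lon/lat) grids.

A :class:`LandscapeRaster` is a rectangular grid of either land-use class
codes or per-cell conductances (relative permeability to animal movement),
georeferenced by the lon/lat of its lower-left corner and per-axis cell
sizes in decimal degrees. Row 0 is the northernmost row (row-major from the
top-left, the raster convention of GIS imagery).

I/O uses the ESRI ASCII grid dialect, a plain-text header followed by the
grid values. Non-square cells are written with the ``dx``/``dy`` header
keywords (the GDAL extension of the format); square cells round-trip through
the classic ``cellsize`` keyword. Rasters in projected coordinate systems
are out of scope: convert to lon/lat (EPSG:4326) first, e.g. with
``gdalwarp -t_srs EPSG:4326``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .geo import haversine

__all__ = [
    "LandscapeRaster",
    "read_ascii_grid",
    "write_ascii_grid",
    "aggregate_raster",
    "apply_conductance",
    "locate_cell",
    "CellSnapWarning",
]


class RasterError(ValueError):
    """Malformed raster file or inconsistent raster operation."""


class CellSnapWarning(UserWarning):
    """A query point fell on an impermeable cell and was snapped."""


@dataclass
class LandscapeRaster:
    """Grid of class codes or conductances with lon/lat georeferencing.

    Parameters
    ----------
    values : (nrows, ncols) array. Class rasters hold integer codes;
        conductance rasters hold non-negative floats.
    xll, yll : lon/lat of the lower-left corner of the grid, degrees.
    dx, dy : cell size along longitude / latitude, degrees (> 0).
    nodata : value marking cells with no data.
    semantics : ``"classes"`` or ``"conductance"``.
    """

    values: np.ndarray
    xll: float
    yll: float
    dx: float
    dy: float
    nodata: float = -9999.0
    semantics: str = "classes"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise RasterError("raster values must be a 2-D array")
        if self.dx <= 0 or self.dy <= 0:
            raise RasterError("cell sizes must be positive")
        if self.semantics not in ("classes", "conductance"):
            raise RasterError(f"unknown raster semantics {self.semantics!r}")
        if self.semantics == "conductance":
            data = self.values[self.values != self.nodata]
            if data.size and np.nanmin(data) < 0:
                raise RasterError("conductance values must be >= 0")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max)."""
        return (self.xll, self.yll,
                self.xll + self.ncols * self.dx,
                self.yll + self.nrows * self.dy)

    def cell_center(self, row, col):
        """Lon/lat of cell centre(s); row 0 is the northern edge."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.xll + (col + 0.5) * self.dx
        lat = self.yll + (self.nrows - 1 - row + 0.5) * self.dy
        return lon, lat

    def cell_index(self, row, col):
        """Flat row-major index used by the transition graph."""
        return np.asarray(row) * self.ncols + np.asarray(col)

    def classes(self) -> np.ndarray:
        """Sorted unique class codes present (nodata excluded)."""
        vals = self.values[self.values != self.nodata]
        return np.unique(vals)


def read_ascii_grid(path, semantics: str = "classes") -> LandscapeRaster:
    """Read an ESRI ASCII grid (.asc/.agr) in geographic coordinates.

    Accepts ``cellsize`` or the ``dx``/``dy`` pair, and ``xllcorner`` /
    ``yllcorner`` or cell-centre registration (``xllcenter``/``yllcenter``,
    converted to corner registration on read).
    """
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    header_keys = {"ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                   "yllcenter", "cellsize", "dx", "dy", "nodata_value"}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in header_keys and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=float))
    for req in ("ncols", "nrows"):
        if req not in header:
            raise RasterError(f"{path}: missing required header field {req!r}")
    if "cellsize" in header:
        dx = dy = header["cellsize"]
    elif "dx" in header and "dy" in header:
        dx, dy = header["dx"], header["dy"]
    else:
        raise RasterError(f"{path}: header must declare cellsize or dx/dy "
                          "(is the geotransform missing?)")
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    elif "xllcenter" in header:
        xll = header["xllcenter"] - dx / 2.0
        yll = header["yllcenter"] - dy / 2.0
    else:
        raise RasterError(f"{path}: missing xllcorner/xllcenter georeferencing")
    if not (-360.0 <= xll <= 360.0 and -90.0 <= yll <= 90.0):
        raise RasterError(
            f"{path}: origin ({xll}, {yll}) is outside lon/lat range; the "
            "grid looks projected — reproject to EPSG:4326 first")
    values = np.concatenate(rows).reshape(int(header["nrows"]), int(header["ncols"]))
    nodata = header.get("nodata_value", -9999.0)
    if semantics == "classes" and np.allclose(values, np.round(values)):
        values = values.astype(int)
        nodata = int(nodata)
    return LandscapeRaster(values, xll, yll, dx, dy, nodata=nodata,
                           semantics=semantics)


def write_ascii_grid(raster: LandscapeRaster, path) -> None:
    """Write an ESRI ASCII grid; uses dx/dy keywords for non-square cells."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xll!r}\n")
        fh.write(f"yllcorner {raster.yll!r}\n")
        if raster.dx == raster.dy:
            fh.write(f"cellsize {raster.dx!r}\n")
        else:
            fh.write(f"dx {raster.dx!r}\n")
            fh.write(f"dy {raster.dy!r}\n")
        fh.write(f"NODATA_value {raster.nodata}\n")
        for row in raster.values:
            fh.write(" ".join(repr(v) if isinstance(v, float) else str(v)
                              for v in row.tolist()) + "\n")


def aggregate_raster(raster: LandscapeRaster, factor_x: int, factor_y: int,
                     rule: str | None = None) -> LandscapeRaster:
    """Block-aggregate to larger cells (coarser resolution).

    ``rule`` defaults to ``"modal"`` for class rasters and ``"mean"`` for
    conductance rasters. Modal ties are broken towards the smallest class
    code. Partial blocks at the south/east edges aggregate over the cells
    available; nodata cells are excluded (an all-nodata block stays nodata).
    """
    if factor_x < 1 or factor_y < 1 or factor_x != int(factor_x) or factor_y != int(factor_y):
        raise RasterError("aggregation factors must be integers >= 1")
    factor_x, factor_y = int(factor_x), int(factor_y)
    if rule is None:
        rule = "modal" if raster.semantics == "classes" else "mean"
    if factor_x == 1 and factor_y == 1:
        return replace(raster, values=raster.values.copy())

    out_rows = -(-raster.nrows // factor_y)
    out_cols = -(-raster.ncols // factor_x)
    out = np.full((out_rows, out_cols), raster.nodata,
                  dtype=float if rule == "mean" else raster.values.dtype)
    # row 0 is the north edge: blocks count down from the top so the
    # lower-left corner (and hence yll) moves only if a partial block exists
    for bi in range(out_rows):
        for bj in range(out_cols):
            block = raster.values[bi * factor_y:(bi + 1) * factor_y,
                                  bj * factor_x:(bj + 1) * factor_x]
            data = block[block != raster.nodata]
            if data.size == 0:
                continue
            if rule == "mean":
                out[bi, bj] = data.mean()
            elif rule == "modal":
                codes, counts = np.unique(data, return_counts=True)
                out[bi, bj] = codes[np.argmax(counts)]  # unique() sorts: ties -> smallest
            else:
                raise RasterError(f"unknown aggregation rule {rule!r}")
    new_dy = raster.dy * factor_y
    # keep the top (north) edge fixed; recompute yll from it
    top = raster.yll + raster.nrows * raster.dy
    return LandscapeRaster(out, raster.xll, top - out_rows * new_dy,
                           raster.dx * factor_x, new_dy,
                           nodata=raster.nodata, semantics=raster.semantics)


def apply_conductance(raster: LandscapeRaster,
                      conductance_map: dict) -> LandscapeRaster:
    """Substitute class codes by conductances; nodata cells become 0.

    Every class present in the raster must be mapped; conductance 0 marks an
    impermeable class (its cells are isolated in the transition graph).
    """
    if raster.semantics != "classes":
        raise RasterError("apply_conductance expects a class raster")
    if not any(v > 0 for v in conductance_map.values()):
        raise RasterError("conductance map must have at least one positive class")
    if any(v < 0 for v in conductance_map.values()):
        raise RasterError("conductances must be >= 0")
    out = np.zeros(raster.values.shape, dtype=float)
    for code in raster.classes():
        # tolerate int or string keys (string keys arrive from JSON configs)
        for key in (code, int(code), str(int(code))):
            if key in conductance_map:
                out[raster.values == code] = conductance_map[key]
                break
        else:
            raise RasterError(f"class {code} has no conductance assigned")
    out[raster.values == raster.nodata] = 0.0
    return LandscapeRaster(out, raster.xll, raster.yll, raster.dx, raster.dy,
                           nodata=-9999.0, semantics="conductance")


def locate_cell(raster: LandscapeRaster, lon: float, lat: float,
                snap_to_conductance: bool = True) -> tuple[int, int]:
    """(row, col) of the cell whose extent contains the point.

    Cell extents are half-open intervals [x, x + dx) x [y, y + dy): a point
    on a shared boundary belongs to the cell whose lower-left corner it is.
    On a conductance raster, a point landing on an impermeable (0) cell is
    snapped to the nearest positive-conductance cell centre and a
    :class:`CellSnapWarning` records the snap distance.
    """
    lon_min, lat_min, lon_max, lat_max = raster.bounds
    if not (lon_min <= lon < lon_max and lat_min <= lat < lat_max):
        raise RasterError(f"point ({lon}, {lat}) outside raster bounds {raster.bounds}")
    # 1e-10-cell epsilon keeps boundary points on the half-open side
    # despite float cancellation in (coord - corner)
    col = int(np.floor((lon - raster.xll) / raster.dx + 1e-10))
    row = raster.nrows - 1 - int(np.floor((lat - raster.yll) / raster.dy + 1e-10))
    col = min(col, raster.ncols - 1)
    row = max(row, 0)
    if (snap_to_conductance and raster.semantics == "conductance"
            and raster.values[row, col] <= 0):
        rows, cols = np.nonzero(raster.values > 0)
        if rows.size == 0:
            raise RasterError("raster has no positive-conductance cells")
        clon, clat = raster.cell_center(rows, cols)
        d = haversine(lon, lat, clon, clat)
        best = int(np.argmin(d))
        warnings.warn(
            f"point ({lon}, {lat}) lies on an impermeable cell; snapped "
            f"{d[best]:.1f} m to cell ({rows[best]}, {cols[best]})",
            CellSnapWarning, stacklevel=2)
        return int(rows[best]), int(cols[best])
    return row, col
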