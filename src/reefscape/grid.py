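"""Digital elevation model container and raster I/O.

A :class:`DEMGrid` holds a single-band elevation raster with square cells,
an optional nodata mask, and a lower-left origin in meters.  All structural
metrics (field of view, refuge density, rugosity) read this container.

Conventions
-----------
* Row ``i`` runs south->north, column ``j`` runs west->east.
* Cell ``(i, j)`` has its *center* at ``origin + ((j + 0.5) c, (i + 0.5) c)``
  where ``c`` is the cell size in meters.  Bilinear interpolation and quadrat
  cropping are defined against cell centers.
* Nodata cells are stored as NaN; any operation whose stencil touches a
  nodata cell raises rather than interpolating across the gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import tifffile

__all__ = [
    "DEMGrid",
    "CrossSectionProfile",
    "read_dem",
    "write_dem",
    "extract_profile",
    "random_cross_section",
    "random_quadrats",
]

#: GeoTIFF tag ids used for minimal georeferencing.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

_ASCII_NODATA = -9999.0


@dataclass
class DEMGrid:
    """Elevation raster with square cells.

    Parameters
    ----------
    elevations
        2D float array of heights in meters; NaN marks nodata.
    cell_size
        Edge length of a (square) pixel in meters.
    origin
        ``(x, y)`` of the lower-left *corner* of the lower-left cell, meters.
    """

    elevations: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.elevations = np.asarray(self.elevations, dtype=float)
        if self.elevations.ndim != 2:
            raise ValueError("elevations must be a 2D array")
        if self.elevations.shape[0] < 2 or self.elevations.shape[1] < 2:
            raise ValueError("DEM must be at least 2x2 cells")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def nodata_mask(self) -> np.ndarray:
        """Boolean mask, True where the cell carries no elevation."""
        return ~np.isfinite(self.elevations)

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevations.shape

    @property
    def extent_x(self) -> float:
        """Grid width along the (long) x axis, meters."""
        return self.shape[1] * self.cell_size

    @property
    def extent_y(self) -> float:
        return self.shape[0] * self.cell_size

    @property
    def valid_area_m2(self) -> float:
        return float((~self.nodata_mask).sum()) * self.cell_size**2

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        c = self.cell_size
        return (self.origin[0] + (j + 0.5) * c, self.origin[1] + (i + 0.5) * c)


@dataclass
class CrossSectionProfile:
    """Ordered (distance, elevation) samples along a straight segment.

    ``distances`` increase strictly from 0 to ``total_length``; ``metadata``
    records placement (endpoints, seed-derived offsets) for reproducibility.
    """

    distances: np.ndarray
    elevations: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.elevations = np.asarray(self.elevations, dtype=float)
        if self.distances.shape != self.elevations.shape:
            raise ValueError("distances and elevations must align")
        if self.distances.size < 2 or np.any(np.diff(self.distances) <= 0):
            raise ValueError("distances must be strictly increasing")
        if self.distances[0] != 0.0:
            raise ValueError("profile must start at distance 0")

    @property
    def total_length(self) -> float:
        return float(self.distances[-1])

    def elevation_at(self, distance: float) -> float:
        """Linear interpolation of substrate height at an arbitrary station."""
        if distance < 0 or distance > self.total_length + 1e-9:
            raise ValueError(f"station {distance} m outside profile")
        return float(np.interp(distance, self.distances, self.elevations))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"distance_m": self.distances, "elevation_m": self.elevations}
        )


# ---------------------------------------------------------------------------
# File I/O


def read_dem(path: str | Path, format: Literal["geotiff", "esri_ascii"] | None = None) -> DEMGrid:
    """Read a DEM from a single-band GeoTIFF or ESRI ASCII grid.

    ``format`` is inferred from the suffix when omitted (.tif/.tiff vs
    .asc/.txt).  Non-square pixels are rejected.
    """
    path = Path(path)
    if format is None:
        format = "geotiff" if path.suffix.lower() in {".tif", ".tiff"} else "esri_ascii"
    if format == "geotiff":
        return _read_geotiff(path)
    if format == "esri_ascii":
        return _read_esri_ascii(path)
    raise ValueError(f"unknown DEM format {format!r}")


def write_dem(grid: DEMGrid, path: str | Path, format: Literal["geotiff", "esri_ascii"] | None = None) -> Path:
    """Write a DEM; round-trips through :func:`read_dem` to float32 precision."""
    path = Path(path)
    if format is None:
        format = "geotiff" if path.suffix.lower() in {".tif", ".tiff"} else "esri_ascii"
    if format == "geotiff":
        _write_geotiff(grid, path)
    elif format == "esri_ascii":
        _write_esri_ascii(grid, path)
    else:
        raise ValueError(f"unknown DEM format {format!r}")
    return path


def _read_geotiff(path: Path) -> DEMGrid:
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            data = page.asarray().astype(float)
            tags = {
                code: page.tags[code].value
                for code in (_TAG_MODEL_PIXEL_SCALE, _TAG_MODEL_TIEPOINT, _TAG_GDAL_NODATA)
                if code in page.tags
            }
    except Exception as exc:  # noqa: BLE001 - surface a format error
        raise ValueError(f"cannot read {path} as GeoTIFF: {exc}") from exc
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster, got shape {data.shape}")
    if _TAG_MODEL_PIXEL_SCALE in tags:
        sx, sy = tags[_TAG_MODEL_PIXEL_SCALE][:2]
        if not math.isclose(sx, sy, rel_tol=1e-6):
            raise ValueError(f"{path}: non-square pixels ({sx} x {sy} m) are not supported")
        cell = float(sx)
    else:
        cell = 1.0
    origin = (0.0, 0.0)
    if _TAG_MODEL_TIEPOINT in tags:
        tp = tags[_TAG_MODEL_TIEPOINT]
        # tie point maps raster (0,0) = top-left corner to world (x, y_top)
        origin = (float(tp[3]), float(tp[4]) - data.shape[0] * cell)
    if _TAG_GDAL_NODATA in tags:
        nodata = float(str(tags[_TAG_GDAL_NODATA]).strip("\x00 "))
        data[data == nodata] = np.nan
    # stored top-down; internal layout is bottom-up
    return DEMGrid(np.flipud(data), cell, origin)


def _write_geotiff(grid: DEMGrid, path: Path) -> None:
    data = np.flipud(grid.elevations).astype(np.float32)
    data = np.where(np.isfinite(data), data, np.float32(_ASCII_NODATA))
    c = grid.cell_size
    y_top = grid.origin[1] + grid.shape[0] * c
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (c, c, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.origin[0], y_top, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(_ASCII_NODATA)),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def _read_esri_ascii(path: Path) -> DEMGrid:
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    try:
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                key = parts[0].lower()
                if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                           "nodata_value", "dx", "dy"}:
                    header[key] = float(parts[1])
                else:
                    rows.append(np.array(parts, dtype=float))
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot read {path} as ESRI ASCII grid: {exc}") from exc
    if "dx" in header and "dy" in header and not math.isclose(header["dx"], header["dy"]):
        raise ValueError(f"{path}: non-square pixels (dx={header['dx']}, dy={header['dy']})")
    if "cellsize" not in header and "dx" not in header:
        raise ValueError(f"{path}: missing cellsize header")
    cell = header.get("cellsize", header.get("dx", 1.0))
    data = np.concatenate(rows).reshape(int(header["nrows"]), int(header["ncols"]))
    nodata = header.get("nodata_value")
    if nodata is not None:
        data[data == nodata] = np.nan
    origin = (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0))
    return DEMGrid(np.flipud(data), float(cell), origin)


def _write_esri_ascii(grid: DEMGrid, path: Path) -> None:
    nrows, ncols = grid.shape
    data = np.where(np.isfinite(grid.elevations), grid.elevations, _ASCII_NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.origin[0]:.6f}\n")
        fh.write(f"yllcorner {grid.origin[1]:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.8f}\n")
        fh.write(f"NODATA_value {_ASCII_NODATA:g}\n")
        for row in np.flipud(data):
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Profiles and quadrats


def bilinear_elevation(grid: DEMGrid, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of elevations at world coordinates.

    Points must lie within the grid extent; within the half-cell margin
    outside the cell-center lattice, the edge value is held constant.
    A stencil touching nodata raises, naming the first offending point.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    nrows, ncols = grid.shape
    c = grid.cell_size
    eps = 1e-9
    xl = x - grid.origin[0]
    yl = y - grid.origin[1]
    if np.any(xl < -eps) or np.any(xl > grid.extent_x + eps) or np.any(yl < -eps) or np.any(yl > grid.extent_y + eps):
        raise ValueError("point outside grid extent")
    u = np.clip(xl / c - 0.5, 0.0, ncols - 1.0)
    v = np.clip(yl / c - 0.5, 0.0, nrows - 1.0)
    j0 = np.clip(np.floor(u).astype(int), 0, ncols - 2)
    i0 = np.clip(np.floor(v).astype(int), 0, nrows - 2)
    fu = u - j0
    fv = v - i0
    z = grid.elevations
    corners = np.stack([z[i0, j0], z[i0, j0 + 1], z[i0 + 1, j0], z[i0 + 1, j0 + 1]])
    bad = ~np.isfinite(corners).all(axis=0)
    if np.any(bad):
        k = int(np.argmax(bad))
        raise ValueError(
            f"interpolation stencil touches nodata at point ({x[k]:.3f}, {y[k]:.3f}) m"
        )
    top = corners[2] * (1 - fu) + corners[3] * fu
    bot = corners[0] * (1 - fu) + corners[1] * fu
    return bot * (1 - fv) + top * fv


def extract_profile(
    grid: DEMGrid,
    start: tuple[float, float],
    end: tuple[float, float],
    step: float,
    metadata: dict | None = None,
) -> CrossSectionProfile:
    """Sample a straight cross-section at regular stations.

    Stations sit at 0, step, 2*step, ... with the segment endpoint always
    included.  Elevations come from bilinear interpolation of the four
    surrounding cell centers; a station over nodata raises.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    sx, sy = start
    ex, ey = end
    length = math.hypot(ex - sx, ey - sy)
    if length <= 0:
        raise ValueError("degenerate segment")
    n = int(math.floor(length / step + 1e-9))
    d = np.arange(n + 1) * step
    if length - d[-1] > 1e-9:
        d = np.append(d, length)
    ux, uy = (ex - sx) / length, (ey - sy) / length
    xs = sx + d * ux
    ys = sy + d * uy
    try:
        zs = bilinear_elevation(grid, xs, ys)
    except ValueError as exc:
        raise ValueError(f"cross-section crosses invalid cells: {exc}") from exc
    meta = {"start": (sx, sy), "end": (ex, ey), "step": step}
    if metadata:
        meta.update(metadata)
    return CrossSectionProfile(d, zs, meta)


def random_cross_section(
    grid: DEMGrid,
    length: float = 10.0,
    rng: np.random.Generator | None = None,
    step: float | None = None,
) -> CrossSectionProfile:
    """Draw a random axis-parallel cross-section of the given length.

    The segment runs parallel to the long (x) axis at a uniformly random
    longitudinal offset and a uniformly random transverse position; both are
    recorded in the profile metadata.  Sampling step defaults to the cell
    size.
    """
    rng = np.random.default_rng(rng)
    if step is None:
        step = grid.cell_size
    max_offset = grid.extent_x - length
    if max_offset < 0:
        raise ValueError(
            f"grid long axis {grid.extent_x:.2f} m is shorter than section length {length} m"
        )
    offset = float(rng.uniform(0.0, max_offset))
    # keep the line on the cell-center lattice transversally
    c = grid.cell_size
    y = float(rng.uniform(0.5 * c, grid.extent_y - 0.5 * c))
    start = (grid.origin[0] + offset, grid.origin[1] + y)
    end = (start[0] + length, start[1])
    return extract_profile(
        grid, start, end, step,
        metadata={"offset_m": offset, "transverse_m": y, "orientation": "long-axis"},
    )


def random_quadrats(
    grid: DEMGrid,
    n: int = 4,
    size: float = 1.0,
    rng: np.random.Generator | None = None,
    margin: float | None = None,
) -> list[DEMGrid]:
    """Crop ``n`` random square quadrats from a DEM.

    The requested edge ``margin`` (default: one quadrat side) is clamped
    per axis to the widest margin the grid can actually afford, so a 1 m
    quadrat remains placeable on a 2 m wide transect; if the quadrat itself
    does not fit even with zero margin, an error suggests a smaller size.
    Placements are logged in each quadrat's ``placement`` attribute-free
    metadata via ``origin``.
    """
    rng = np.random.default_rng(rng)
    if margin is None:
        margin = size
    c = grid.cell_size
    ncells = int(round(size / c))
    if ncells < 1:
        raise ValueError("quadrat smaller than one cell")
    nrows, ncols = grid.shape
    out: list[DEMGrid] = []
    lims = []
    for dim in (nrows, ncols):
        avail = dim - ncells
        if avail < 0:
            raise ValueError(
                f"quadrat of {size} m does not fit in grid; use a smaller size"
            )
        m = min(int(round(margin / c)), avail // 2)
        lims.append((m, dim - m - ncells))
    for _ in range(n):
        i0 = int(rng.integers(lims[0][0], lims[0][1] + 1))
        j0 = int(rng.integers(lims[1][0], lims[1][1] + 1))
        window = grid.elevations[i0 : i0 + ncells, j0 : j0 + ncells]
        if np.any(~np.isfinite(window)):
            raise ValueError("quadrat placement touches nodata cells")
        origin = (grid.origin[0] + j0 * c, grid.origin[1] + i0 * c)
        out.append(DEMGrid(window.copy(), c, origin))
    return out
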