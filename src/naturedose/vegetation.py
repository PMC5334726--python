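"""Neighbourhood vegetation intensity from NDVI and canopy-height rasters.

The intensity component of the nature dose is the percentage of tall
vegetation within a fixed-radius buffer (default 250 m) around a point
(e.g. the centroid of a respondent's postcode).  A pixel is "tall
vegetation" when NDVI > 0.2 and the canopy height exceeds 0.7 m; both
inequalities are strict.  A pixel belongs to the buffer when its *centre*
lies within the radius of the point (centre-inclusion, the common
zonal-statistics convention).

Rasters are plain in-memory grids with a metric, projected coordinate
system; no reprojection is performed.  File I/O uses the ESRI ASCII grid
format, which round-trips through plain text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RasterGrid",
    "VegetationMask",
    "read_ascii_grid",
    "write_ascii_grid",
    "compute_ndvi",
    "classify_vegetation",
    "percent_cover_in_buffer",
    "cover_for_points",
]

DEFAULT_NODATA = -9999.0


@dataclass
class RasterGrid:
    """A single-band raster on a regular metric grid.

    ``values[0, :]`` is the northernmost (top) row.  ``origin_x``/``origin_y``
    are the coordinates of the lower-left corner of the grid, in metres.
    """

    values: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    pixel_size: float = 2.0
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata

    def pixel_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) centre coordinates for every pixel, same shape as values."""
        nrows, ncols = self.values.shape
        xs = self.origin_x + (np.arange(ncols) + 0.5) * self.pixel_size
        ys = self.origin_y + (nrows - np.arange(nrows) - 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.origin_x, other.origin_x)
            and np.isclose(self.origin_y, other.origin_y)
            and np.isclose(self.pixel_size, other.pixel_size)
        )


@dataclass
class VegetationMask:
    """Boolean tall-vegetation classification aligned to its source grids.

    ``valid`` marks pixels where both inputs carried data; ``nodata_count``
    tallies pixels excluded because either input was nodata.
    """

    values: np.ndarray
    valid: np.ndarray
    origin_x: float
    origin_y: float
    pixel_size: float
    nodata_count: int = 0

    def as_grid(self) -> RasterGrid:
        """The mask as a 0/1 raster with nodata where inputs were nodata."""
        out = np.where(self.valid, self.values.astype(float), DEFAULT_NODATA)
        return RasterGrid(out, self.origin_x, self.origin_y, self.pixel_size)


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc) file."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ASCII grid header field {key!r}")
    values = np.loadtxt(lines[n_header:], dtype=float, ndmin=2)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path}: data shape {values.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    return RasterGrid(
        values,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        pixel_size=header["cellsize"],
        nodata=header.get("nodata_value", DEFAULT_NODATA),
    )


def write_ascii_grid(grid: RasterGrid, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid (.asc) file."""
    path = Path(path)
    nrows, ncols = grid.shape
    with path.open("w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.origin_x:.6f}\n")
        fh.write(f"yllcorner {grid.origin_y:.6f}\n")
        fh.write(f"cellsize {grid.pixel_size:.6f}\n")
        fh.write(f"NODATA_value {grid.nodata:.6f}\n")
        np.savetxt(fh, grid.values, fmt="%.6g")


def _require_aligned(a: RasterGrid, b: RasterGrid, what: str) -> None:
    if not a.aligned_with(b):
        raise ValueError(
            f"{what}: grids are not aligned "
            f"(shapes {a.shape} vs {b.shape}, origins "
            f"({a.origin_x},{a.origin_y}) vs ({b.origin_x},{b.origin_y}), "
            f"pixel sizes {a.pixel_size} vs {b.pixel_size})"
        )


def compute_ndvi(nir: RasterGrid, red: RasterGrid) -> RasterGrid:
    """Normalised Difference Vegetation Index, (NIR − Red)/(NIR + Red).

    Pixels where the band sum is zero, or where either band is nodata,
    become nodata in the result.
    """
    _require_aligned(nir, red, "compute_ndvi")
    denom = nir.values + red.values
    valid = nir.valid_mask() & red.valid_mask() & (denom != 0)
    out = np.full(nir.shape, DEFAULT_NODATA)
    np.divide(nir.values - red.values, denom, out=out, where=valid)
    return RasterGrid(out, nir.origin_x, nir.origin_y, nir.pixel_size)


def classify_vegetation(
    ndvi: RasterGrid,
    height: RasterGrid,
    ndvi_threshold: float = 0.2,
    height_threshold_m: float = 0.7,
) -> VegetationMask:
    """Classify tall vegetation: NDVI > threshold AND height > threshold.

    Both comparisons are strict.  Pixels with nodata in either input are
    classified False and counted in ``nodata_count``.
    """
    _require_aligned(ndvi, height, "classify_vegetation")
    valid = ndvi.valid_mask() & height.valid_mask()
    mask = valid & (ndvi.values > ndvi_threshold) & (height.values > height_threshold_m)
    return VegetationMask(
        values=mask,
        valid=valid,
        origin_x=ndvi.origin_x,
        origin_y=ndvi.origin_y,
        pixel_size=ndvi.pixel_size,
        nodata_count=int((~valid).sum()),
    )


def percent_cover_in_buffer(
    mask: VegetationMask,
    point_x: float,
    point_y: float,
    radius_m: float = 250.0,
) -> float:
    """Percent vegetated pixels within ``radius_m`` of a point.

    A pixel is in the buffer iff its centre lies within the radius
    (Euclidean distance <= radius).  The denominator counts only valid
    (non-nodata) in-buffer pixels.
    """
    if radius_m <= 0:
        raise ValueError(f"radius must be positive, got {radius_m}")
    if not (np.isfinite(point_x) and np.isfinite(point_y)):
        raise ValueError("point coordinates must be finite")
    nrows, ncols = mask.values.shape
    px = mask.pixel_size
    # bounding-box prefilter: only rows/cols whose centres can be in range
    xs = mask.origin_x + (np.arange(ncols) + 0.5) * px
    ys = mask.origin_y + (nrows - np.arange(nrows) - 0.5) * px
    cols = np.nonzero(np.abs(xs - point_x) <= radius_m)[0]
    rows = np.nonzero(np.abs(ys - point_y) <= radius_m)[0]
    if len(cols) == 0 or len(rows) == 0:
        raise ValueError(
            f"buffer of radius {radius_m} m around ({point_x}, {point_y}) "
            "does not intersect the raster"
        )
    dx = xs[cols] - point_x
    dy = ys[rows] - point_y
    inside = (dy[:, None] ** 2 + dx[None, :] ** 2) <= radius_m**2
    sub_valid = mask.valid[np.ix_(rows, cols)]
    eligible = inside & sub_valid
    n_eligible = int(eligible.sum())
    if n_eligible == 0:
        raise ValueError(
            f"no valid pixels within {radius_m} m of ({point_x}, {point_y})"
        )
    n_veg = int((mask.values[np.ix_(rows, cols)] & eligible).sum())
    return 100.0 * n_veg / n_eligible


def cover_for_points(
    mask: VegetationMask,
    points: pd.DataFrame,
    radius_m: float = 250.0,
    id_col: str = "respondent_id",
    x_col: str = "x",
    y_col: str = "y",
) -> pd.DataFrame:
    """Per-point percent cover for a table of (id, x, y) locations.

    Points whose buffer misses the raster entirely get NaN cover.
    """
    covers = []
    for _, row in points.iterrows():
        try:
            cov = percent_cover_in_buffer(mask, row[x_col], row[y_col], radius_m)
        except ValueError:
            cov = float("nan")
        covers.append(cov)
    return pd.DataFrame(
        {id_col: points[id_col].values, "vegetation_cover_pct": covers}
    )
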