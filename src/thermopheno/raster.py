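"""Georeferenced temperature rasters and flight-geometry utilities.

A radiometric mosaic is a single-band grid of surface temperatures in °C.
The georeference is a 6-parameter affine mapping 0-based pixel indices
(col, row) to world coordinates (x, y) in metres, with the convention that
the affine maps pixel CENTERS.  Nodata is encoded as NaN; integer rasters
are not supported.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "Affine",
    "RadiometricMosaic",
    "GroundControlPoint",
    "FlightContext",
    "read_mosaic",
    "write_mosaic",
    "estimate_affine_from_gcps",
    "read_gcps",
    "select_frames",
    "ground_sample_distance",
]


@dataclass(frozen=True)
class Affine:
    """x = a*col + b*row + c ; y = d*col + e*row + f, (col,row) at pixel centers."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def __call__(self, col, row):
        return (self.a * col + self.b * row + self.c,
                self.d * col + self.e * row + self.f)

    @property
    def determinant(self) -> float:
        return self.a * self.e - self.b * self.d

    def inverse(self) -> "Affine":
        det = self.determinant
        if det == 0:
            raise ValueError("affine transform is singular")
        ia, ib = self.e / det, -self.b / det
        id_, ie = -self.d / det, self.a / det
        return Affine(ia, ib, -(ia * self.c + ib * self.f),
                      id_, ie, -(id_ * self.c + ie * self.f))

    def world_to_pixel(self, x, y):
        inv = self.inverse()
        return inv(x, y)

    @classmethod
    def north_up(cls, x_center0: float, y_center0: float, pixel_size: float) -> "Affine":
        """Axis-aligned grid: row 0 at the northern edge, y decreasing with row."""
        return cls(pixel_size, 0.0, x_center0, 0.0, -pixel_size, y_center0)


@dataclass
class RadiometricMosaic:
    """Single-band temperature raster (°C) with affine georeference.

    ``values`` holds NaN at nodata pixels; ``mask`` is True where valid.
    """

    values: np.ndarray
    transform: Affine

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError("mosaic values must be a 2D array")
        if self.transform.determinant == 0:
            raise ValueError("affine transform must be invertible")

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def shape(self):
        return self.values.shape

    @property
    def pixel_size(self) -> float:
        return math.sqrt(abs(self.transform.determinant))

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def pixel_centers(self):
        """World coordinates of every pixel center as (X, Y) 2D arrays."""
        nrows, ncols = self.values.shape
        cols, rows = np.meshgrid(np.arange(ncols), np.arange(nrows))
        return self.transform(cols, rows)


@dataclass(frozen=True)
class GroundControlPoint:
    col: float
    row: float
    x: float
    y: float

    def __post_init__(self):
        if not all(np.isfinite([self.col, self.row, self.x, self.y])):
            raise ValueError("GCP coordinates must be finite")


@dataclass(frozen=True)
class FlightContext:
    """Flight geometry of the thermal survey."""

    air_temperature: float = 28.75   # °C at flight time
    elevation: float = 25.0          # m above ground
    ifov_mrad: float = 2.78          # instantaneous field of view
    sensor_px: tuple = (320, 256)    # (horizontal, vertical)

    def __post_init__(self):
        if self.elevation <= 0 or self.ifov_mrad <= 0:
            raise ValueError("elevation and IFOV must be positive")


# ---------------------------------------------------------------------------
# raster I/O

_GEOTIFF_PIXELSCALE = 33550
_GEOTIFF_TIEPOINT = 33922


def write_mosaic(mosaic: RadiometricMosaic, path) -> None:
    """Write as single-band float32 GeoTIFF (.tif) or ESRI ASCII grid (.asc)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        _write_geotiff(mosaic, path)
    elif suffix in {".asc", ".grd", ".txt"}:
        _write_ascii_grid(mosaic, path)
    else:
        raise ValueError(f"unsupported raster format: {path.suffix!r}")


def read_mosaic(path) -> RadiometricMosaic:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        return _read_geotiff(path)
    if suffix in {".asc", ".grd", ".txt"}:
        return _read_ascii_grid(path)
    raise ValueError(f"unsupported raster format: {path.suffix!r}")


def _write_geotiff(mosaic: RadiometricMosaic, path: Path) -> None:
    t = mosaic.transform
    if t.b != 0 or t.d != 0:
        raise ValueError("GeoTIFF writer supports axis-aligned transforms only")
    # GeoTIFF tiepoint refers to the outer corner of pixel (0,0) (raster-as-area);
    # our affine addresses pixel centers, hence the half-pixel shift.
    sx, sy = t.a, -t.e
    corner_x = t.c - sx / 2.0
    corner_y = t.f + sy / 2.0
    extratags = [
        (_GEOTIFF_PIXELSCALE, "d", 3, (sx, sy, 0.0)),
        (_GEOTIFF_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, corner_x, corner_y, 0.0)),
    ]
    tifffile.imwrite(path, mosaic.values.astype(np.float32), extratags=extratags)


def _read_geotiff(path: Path) -> RadiometricMosaic:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(np.float32)
        tags = page.tags
        if _GEOTIFF_PIXELSCALE not in tags or _GEOTIFF_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing GeoTIFF georeference tags")
        sx, sy, _ = tags[_GEOTIFF_PIXELSCALE].value
        tie = tags[_GEOTIFF_TIEPOINT].value
        _, _, _, corner_x, corner_y, _ = tie[:6]
    transform = Affine.north_up(corner_x + sx / 2.0, corner_y - sy / 2.0, sx)
    if sx != sy:
        transform = Affine(sx, 0.0, corner_x + sx / 2.0,
                           0.0, -sy, corner_y - sy / 2.0)
    return RadiometricMosaic(values, transform)


def _write_ascii_grid(mosaic: RadiometricMosaic, path: Path) -> None:
    t = mosaic.transform
    if t.b != 0 or t.d != 0 or abs(abs(t.a) - abs(t.e)) > 1e-12 * abs(t.a):
        raise ValueError("ASCII grid requires square, axis-aligned pixels")
    nrows, ncols = mosaic.shape
    cs = t.a
    xll = t.c - cs / 2.0
    yll = (t.f + t.e * (nrows - 1)) - cs / 2.0
    nodata = -9999.0
    vals = np.where(np.isfinite(mosaic.values), mosaic.values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {float(xll)!r}\n")
        fh.write(f"yllcorner {float(yll)!r}\n")
        fh.write(f"cellsize {float(cs)!r}\n")
        fh.write(f"NODATA_value {float(nodata)!r}\n")
        np.savetxt(fh, vals, fmt="%.9g")


def _read_ascii_grid(path: Path) -> RadiometricMosaic:
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.strip().partition(" ")
            key = key.lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"}:
                header[key] = float(value)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        values = np.loadtxt(fh, dtype=np.float32, ndmin=2)
    for required in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if required not in header:
            raise ValueError(f"{path}: ASCII grid header missing {required}")
    nrows = int(header["nrows"])
    ncols = int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise ValueError(f"{path}: grid shape {values.shape} does not match header")
    if "nodata_value" in header:
        values[values == np.float32(header["nodata_value"])] = np.nan
    cs = header["cellsize"]
    x0 = header["xllcorner"] + cs / 2.0
    y0 = header["yllcorner"] + (nrows - 0.5) * cs
    return RadiometricMosaic(values, Affine.north_up(x0, y0, cs))


# ---------------------------------------------------------------------------
# georeferencing from ground control points

def estimate_affine_from_gcps(gcps) -> tuple[Affine, float]:
    """Least-squares 6-parameter affine from image (col,row) to world (x,y).

    Returns the affine and the RMSE (m) of reprojected world coordinates.
    Requires at least 3 non-collinear points.
    """
    gcps = list(gcps)
    if len(gcps) < 3:
        raise ValueError("at least 3 GCPs are required")
    A = np.array([[g.col, g.row, 1.0] for g in gcps])
    if np.linalg.matrix_rank(A) < 3:
        raise ValueError("GCPs are collinear; affine is underdetermined")
    bx = np.array([g.x for g in gcps])
    by = np.array([g.y for g in gcps])
    px, *_ = np.linalg.lstsq(A, bx, rcond=None)
    py, *_ = np.linalg.lstsq(A, by, rcond=None)
    affine = Affine(px[0], px[1], px[2], py[0], py[1], py[2])
    rx = A @ px - bx
    ry = A @ py - by
    rmse = float(np.sqrt(np.mean(rx**2 + ry**2)))
    return affine, rmse


def read_gcps(path):
    """Read GCPs from CSV with header col,row,x_m,y_m."""
    out = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            out.append(GroundControlPoint(float(rec["col"]), float(rec["row"]),
                                          float(rec["x_m"]), float(rec["y_m"])))
    return out


# ---------------------------------------------------------------------------
# flight utilities

def select_frames(n_total: int, step: int) -> np.ndarray:
    """1-based indices of every ``step``-th frame, keeping the first.

    The count is floor((n_total-1)/step) + 1; e.g. 7836 frames subsampled
    every 20th yield 392.
    """
    if n_total < 1 or step < 1:
        raise ValueError("n_total and step must be positive")
    return np.arange(1, n_total + 1, step)


def ground_sample_distance(context: FlightContext) -> tuple[float, tuple[float, float]]:
    """Ground sample distance (m/px) and sensor footprint (m × m).

    gsd = elevation × IFOV; the small-angle approximation is exact to the
    precision the IFOV is quoted at.
    """
    gsd = context.elevation * context.ifov_mrad * 1e-3
    nx, ny = context.sensor_px
    return gsd, (gsd * nx, gsd * ny)
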