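"""Georeferenced raster containers and plot-polygon I/O.

Rasters are plain GeoTIFFs: pixel data handled by :mod:`tifffile`, with the
standard GeoTIFF georeferencing tags (ModelPixelScale, ModelTiepoint, a minimal
GeoKeyDirectory carrying an EPSG code) and GDAL's nodata tag. Plot boundaries
are GeoJSON polygons with a ``plot_id`` property.

The affine transform follows the raster convention: the map coordinates of the
*upper-left corner* of pixel ``(row, col)`` are ``(c + a*col + b*row,
f + d*col + e*row)``; pixel centers sit half a pixel further. Pixel inclusion
when clipping to a plot is decided by the pixel-center-in-polygon rule so that
per-plot pixel counts (and hence area fractions) are unambiguous integers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import Polygon, mapping, shape

from .errors import CRSMismatchError, PlotClipError, PlotGeometryError, RasterFormatError

MULTISPECTRAL_BANDS = ("blue", "green", "red", "rededge", "nir")
RGB_BANDS = ("R", "G", "B")

# TIFF tag codes of the GeoTIFF subset we read and write
_TAG_PIXELSCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113

REFLECTANCE_RANGE = (-0.05, 1.2)


@dataclass(frozen=True)
class Affine:
    """Six-parameter affine georeference (x = a*col + b*row + c, y = d*col + e*row + f)."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def xy(self, row, col, offset: float = 0.5):
        """Map coordinates of pixel ``(row, col)``; default at the pixel center."""
        col = np.asarray(col, dtype=float) + offset
        row = np.asarray(row, dtype=float) + offset
        return self.a * col + self.b * row + self.c, self.d * col + self.e * row + self.f

    def shifted(self, row0: int, col0: int) -> "Affine":
        """Transform of a window whose origin is at pixel (row0, col0)."""
        x0, y0 = self.xy(row0, col0, offset=0.0)
        return Affine(self.a, self.b, x0, self.d, self.e, y0)

    @property
    def resolution(self) -> tuple[float, float]:
        return abs(self.a), abs(self.e)

    def to_tuple(self) -> tuple[float, ...]:
        return (self.a, self.b, self.c, self.d, self.e, self.f)


def _check_reflectance(values: np.ndarray, mask: np.ndarray, band: str) -> None:
    lo, hi = REFLECTANCE_RANGE
    bad = int(np.sum((values[mask] < lo) | (values[mask] > hi)))
    if bad:
        warnings.warn(
            f"band {band!r}: {bad} reflectance values outside [{lo}, {hi}]",
            stacklevel=3,
        )


@dataclass
class BandStack:
    """Co-registered named bands sharing one grid, transform and validity mask.

    ``mask`` is True where the pixel is valid; invalid pixels correspond to the
    ``nodata`` sentinel on disk. ``is_reflectance`` flags calibrated stacks.
    """

    bands: dict[str, np.ndarray]
    transform: Affine
    crs: str | None = None
    nodata: float | None = None
    mask: np.ndarray | None = None
    is_reflectance: bool = False

    def __post_init__(self):
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) != 1:
            raise RasterFormatError(f"bands have differing shapes: {shapes}")
        if self.mask is None:
            self.mask = np.ones(next(iter(shapes)), dtype=bool)
        if self.mask.shape != next(iter(shapes)):
            raise RasterFormatError("mask shape differs from band shape")
        if self.is_reflectance:
            for name, vals in self.bands.items():
                _check_reflectance(vals, self.mask, name)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape

    @property
    def band_names(self) -> tuple[str, ...]:
        return tuple(self.bands)

    @property
    def resolution(self) -> tuple[float, float]:
        return self.transform.resolution

    def band(self, name: str) -> np.ndarray:
        try:
            return self.bands[name]
        except KeyError:
            raise RasterFormatError(
                f"band {name!r} not in stack (has {sorted(self.bands)})"
            ) from None


@dataclass
class ElevationRaster:
    """Single-band elevation surface: DSM, bare-earth DEM, or derived CHM."""

    values: np.ndarray
    kind: str  # DSM | DEM | CHM
    transform: Affine
    crs: str | None = None
    nodata: float | None = None
    mask: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("DSM", "DEM", "CHM"):
            raise RasterFormatError(f"unknown elevation kind {self.kind!r}")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class PlotGeometry:
    """One experimental unit: a valid polygon in the raster CRS plus identifier."""

    plot_id: str
    polygon: Polygon
    group: str | None = None
    crs: str | None = None

    def __post_init__(self):
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise PlotGeometryError(
                f"plot {self.plot_id!r}: polygon invalid or degenerate"
            )

    def shrunk(self, distance: float) -> "PlotGeometry":
        """Inward-buffered copy (e.g. to drop plot-border pixels)."""
        poly = self.polygon.buffer(-abs(distance))
        if poly.is_empty or poly.area <= 0:
            raise PlotGeometryError(
                f"plot {self.plot_id!r}: shrink by {distance} leaves empty polygon"
            )
        return replace(self, polygon=poly)


# ---------------------------------------------------------------------------
# GeoTIFF I/O


def _geotags(transform: Affine, crs: str | None, nodata) -> list:
    sx, sy = transform.a, -transform.e  # north-up rasters store a positive y scale
    tags = [
        (_TAG_PIXELSCALE, "d", 3, (float(sx), float(sy), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(transform.c), float(transform.f), 0.0)),
    ]
    keys = [1, 1, 0, 2, 1024, 0, 1, 1, 1025, 0, 1, 1]  # projected CRS, PixelIsArea
    if crs and crs.upper().startswith("EPSG:"):
        epsg = int(crs.split(":")[1])
        keys[3] += 1
        keys += [3072, 0, 1, epsg]
    tags.append((_TAG_GEOKEYS, "H", len(keys), tuple(keys)))
    if nodata is not None:
        nd = repr(float(nodata)) if not float(nodata).is_integer() else str(int(nodata))
        tags.append((_TAG_GDAL_NODATA, "s", 0, nd))
    return tags


def _parse_geotags(page) -> tuple[Affine, str | None, float | None]:
    if _TAG_PIXELSCALE not in page.tags or _TAG_TIEPOINT not in page.tags:
        raise RasterFormatError("raster lacks GeoTIFF georeferencing tags")
    sx, sy, _ = page.tags[_TAG_PIXELSCALE].value
    tp = page.tags[_TAG_TIEPOINT].value
    x0, y0 = tp[3] - tp[0] * sx, tp[4] + tp[1] * sy
    transform = Affine(sx, 0.0, x0, 0.0, -sy, y0)
    crs = None
    if _TAG_GEOKEYS in page.tags:
        keys = page.tags[_TAG_GEOKEYS].value
        for k in range(4, len(keys), 4):
            if keys[k] == 3072:
                crs = f"EPSG:{keys[k + 3]}"
    nodata = None
    if _TAG_GDAL_NODATA in page.tags:
        try:
            nodata = float(page.tags[_TAG_GDAL_NODATA].value)
        except ValueError:
            pass
    return transform, crs, nodata


def _read_tiff(path) -> tuple[np.ndarray, Affine, str | None, float | None]:
    path = Path(path)
    if not path.exists():
        raise RasterFormatError(f"raster file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        transform, crs, nodata = _parse_geotags(tif.pages[0])
    return data, transform, crs, nodata


def read_raster(
    path,
    band_names: Sequence[str],
    nodata: float | None = None,
    is_reflectance: bool = False,
) -> BandStack:
    """Read a multiband GeoTIFF, naming bands per ``band_names`` (in file order)."""
    data, transform, crs, file_nodata = _read_tiff(path)
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != len(band_names):
        raise RasterFormatError(
            f"{path}: file has {data.shape[0]} bands but band map declares "
            f"{len(band_names)} ({list(band_names)})"
        )
    nodata = nodata if nodata is not None else file_nodata
    mask = np.ones(data.shape[1:], dtype=bool)
    if nodata is not None:
        mask &= ~np.any(data == nodata, axis=0)
    bands = {name: data[i].astype(np.float64) for i, name in enumerate(band_names)}
    return BandStack(bands, transform, crs, nodata, mask, is_reflectance)


def read_elevation(path, kind: str, nodata: float | None = None) -> ElevationRaster:
    data, transform, crs, file_nodata = _read_tiff(path)
    if data.ndim != 2:
        raise RasterFormatError(f"{path}: elevation raster must be single-band")
    nodata = nodata if nodata is not None else file_nodata
    mask = np.ones(data.shape, dtype=bool)
    if nodata is not None:
        mask &= data != nodata
    return ElevationRaster(data.astype(np.float64), kind, transform, crs, nodata, mask)


def write_raster(path, stack: BandStack, dtype=None) -> None:
    """Write a BandStack as a GeoTIFF; invalid pixels are filled with nodata."""
    arr = np.stack([stack.bands[b] for b in stack.band_names])
    if stack.nodata is not None:
        arr = arr.copy()
        arr[:, ~stack.mask] = stack.nodata
    if dtype is not None:
        arr = arr.astype(dtype)
    if arr.shape[0] == 1:
        arr = arr[0]
    tifffile.imwrite(
        path,
        arr,
        photometric="minisblack",
        planarconfig="separate" if arr.ndim == 3 else None,
        extratags=_geotags(stack.transform, stack.crs, stack.nodata),
    )


def write_elevation(path, raster: ElevationRaster, dtype=None) -> None:
    arr = raster.values
    if raster.nodata is not None:
        arr = arr.copy()
        arr[~raster.mask] = raster.nodata
    if dtype is not None:
        arr = arr.astype(dtype)
    tifffile.imwrite(path, arr, extratags=_geotags(raster.transform, raster.crs, raster.nodata))


# ---------------------------------------------------------------------------
# Plot polygons


def read_plots(path) -> list[PlotGeometry]:
    """Read plot polygons from a GeoJSON FeatureCollection, ordered by plot_id.

    Each feature needs a ``plot_id`` (or ``id``) property; an optional ``group``
    property labels the experiment (e.g. variety vs nitrogen treatment).
    """
    path = Path(path)
    gj = json.loads(path.read_text())
    crs = None
    if isinstance(gj.get("crs"), dict):
        name = gj["crs"].get("properties", {}).get("name", "")
        if "EPSG" in name.upper():
            crs = "EPSG:" + name.rsplit(":", 1)[-1]
    plots, bad = [], []
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        pid = str(props.get("plot_id", props.get("id", "")))
        geom = shape(feat["geometry"])
        if not pid or geom.is_empty or not geom.is_valid or geom.area <= 0:
            bad.append(pid or "<missing id>")
            continue
        plots.append(PlotGeometry(pid, geom, props.get("group"), crs))
    if bad:
        raise PlotGeometryError(f"invalid plot features: {bad}")
    ids = [p.plot_id for p in plots]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise PlotGeometryError(f"duplicate plot_id values: {dupes}")
    if not plots:
        warnings.warn(f"{path}: empty plot collection", stacklevel=2)
    return sorted(plots, key=lambda p: p.plot_id)


def write_plots(path, plots: Sequence[PlotGeometry], crs: str | None = None) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"plot_id": p.plot_id, **({"group": p.group} if p.group else {})},
            "geometry": mapping(p.polygon),
        }
        for p in plots
    ]
    gj: dict = {"type": "FeatureCollection", "features": features}
    crs = crs or next((p.crs for p in plots if p.crs), None)
    if crs:
        gj["crs"] = {"type": "name", "properties": {"name": f"urn:ogc:def:crs:{crs}"}}
    Path(path).write_text(json.dumps(gj, indent=1))


# ---------------------------------------------------------------------------
# Clipping


def _check_crs(raster_crs: str | None, plot: PlotGeometry) -> None:
    if raster_crs and plot.crs and raster_crs != plot.crs:
        raise CRSMismatchError(
            f"plot {plot.plot_id!r} CRS {plot.crs} != raster CRS {raster_crs}; "
            "reproject the plots explicitly before clipping"
        )


def _plot_window(transform: Affine, shape: tuple[int, int], plot: PlotGeometry):
    """Window indices and pixel-center containment mask for one plot."""
    nrows, ncols = shape
    minx, miny, maxx, maxy = plot.polygon.bounds
    # invert the (axis-aligned) transform for the bounding box
    c0 = int(np.floor((minx - transform.c) / transform.a))
    c1 = int(np.ceil((maxx - transform.c) / transform.a))
    r0 = int(np.floor((maxy - transform.f) / transform.e))
    r1 = int(np.ceil((miny - transform.f) / transform.e))
    r0, r1 = max(r0, 0), min(r1, nrows)
    c0, c1 = max(c0, 0), min(c1, ncols)
    if r0 >= r1 or c0 >= c1:
        raise PlotClipError(plot.plot_id, "polygon does not intersect the raster extent")
    rows, cols = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    xs, ys = transform.xy(rows, cols)
    inside = shapely.contains_xy(plot.polygon, xs.ravel(), ys.ravel()).reshape(rows.shape)
    if not inside.any():
        raise PlotClipError(plot.plot_id, "no pixel centers fall inside the polygon")
    return (r0, r1, c0, c1), inside


def clip_to_plot(stack: BandStack, plot: PlotGeometry) -> BandStack:
    """Restrict a stack to one plot: outside pixel centers become nodata."""
    _check_crs(stack.crs, plot)
    (r0, r1, c0, c1), inside = _plot_window(stack.transform, stack.shape, plot)
    bands = {n: v[r0:r1, c0:c1].copy() for n, v in stack.bands.items()}
    mask = stack.mask[r0:r1, c0:c1] & inside
    if not mask.any():
        raise PlotClipError(plot.plot_id, "no valid pixels inside the polygon")
    return BandStack(
        bands,
        stack.transform.shifted(r0, c0),
        stack.crs,
        stack.nodata,
        mask,
        stack.is_reflectance,
    )


def clip_elevation(raster: ElevationRaster, plot: PlotGeometry) -> ElevationRaster:
    _check_crs(raster.crs, plot)
    (r0, r1, c0, c1), inside = _plot_window(raster.transform, raster.shape, plot)
    mask = raster.mask[r0:r1, c0:c1] & inside
    if not mask.any():
        raise PlotClipError(plot.plot_id, "no valid pixels inside the polygon")
    return ElevationRaster(
        raster.values[r0:r1, c0:c1].copy(),
        raster.kind,
        raster.transform.shifted(r0, c0),
        raster.crs,
        raster.nodata,
        mask,
    )
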