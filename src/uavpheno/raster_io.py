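"""Georeferenced raster and plot-polygon I/O.

Rasters are single-band GeoTIFFs with a north-up, unrotated affine
transform; all lengths are metres internally.  The reader/writer pair
speaks the standard GeoTIFF tags (ModelPixelScale, ModelTiepoint,
GeoKeyDirectory, GDAL_NODATA) on top of :mod:`tifffile`.  Plot
boundaries are GeoJSON feature collections handled with :mod:`shapely`.

Conventions
-----------
* Raster indexing is 0-based ``(row, col)`` with row 0 at the north edge.
* World coordinates map to pixel centres: the centre of pixel
  ``(row, col)`` is ``(origin_x + (col + 0.5) * gsd_x,
  origin_y - (row + 0.5) * gsd_y)`` where the origin is the outer
  corner of the top-left pixel.
* CRS equality is by identifier string (``"EPSG:32654"``); reprojection
  is out of scope — products of one flight share a CRS.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import Polygon, shape as shapely_shape, mapping as shapely_mapping

logger = logging.getLogger(__name__)

# GeoTIFF tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_MODEL_TRANSFORMATION = 34264
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids
_KEY_MODEL_TYPE = 1024          # 1 = projected, 2 = geographic
_KEY_RASTER_TYPE = 1025         # 1 = PixelIsArea
_KEY_GEOGRAPHIC_TYPE = 2048
_KEY_PROJECTED_CS_TYPE = 3072


class RasterIOError(Exception):
    """Raised for unreadable or unsupported raster/vector inputs."""


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass(frozen=True)
class GridTransform:
    """North-up affine transform: origin at the top-left pixel corner."""

    origin_x: float
    origin_y: float
    gsd_x: float
    gsd_y: float

    def __post_init__(self) -> None:
        if not (self.gsd_x > 0 and self.gsd_y > 0):
            raise ValidationError(
                f"ground sampling distance must be positive, got "
                f"({self.gsd_x}, {self.gsd_y})"
            )

    @property
    def pixel_area(self) -> float:
        return self.gsd_x * self.gsd_y

    def pixel_centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Return 1-D arrays of column-centre x and row-centre y coordinates."""
        rows, cols = shape
        xs = self.origin_x + (np.arange(cols) + 0.5) * self.gsd_x
        ys = self.origin_y - (np.arange(rows) + 0.5) * self.gsd_y
        return xs, ys

    def world_to_pixel(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map world coordinates to (row, col) indices of the containing pixel."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.gsd_x).astype(np.int64)
        row = np.floor((self.origin_y - np.asarray(y)) / self.gsd_y).astype(np.int64)
        return row, col

    def bounds(self, shape: tuple[int, int]) -> tuple[float, float, float, float]:
        rows, cols = shape
        return (
            self.origin_x,
            self.origin_y - rows * self.gsd_y,
            self.origin_x + cols * self.gsd_x,
            self.origin_y,
        )

    def isclose(self, other: "GridTransform", rel_tol: float = 1e-9) -> bool:
        return (
            math.isclose(self.origin_x, other.origin_x, rel_tol=rel_tol, abs_tol=1e-9)
            and math.isclose(self.origin_y, other.origin_y, rel_tol=rel_tol, abs_tol=1e-9)
            and math.isclose(self.gsd_x, other.gsd_x, rel_tol=rel_tol)
            and math.isclose(self.gsd_y, other.gsd_y, rel_tol=rel_tol)
        )


@dataclass
class RasterGrid:
    """A 2-D value grid with geotransform, nodata sentinel and CRS tag.

    ``values`` holds DSM altitudes in metres, unitless reflectances in
    [0, 1], or mask values in {0, 1}.
    """

    values: np.ndarray
    transform: GridTransform
    nodata: float | None = None
    crs: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValidationError(
                f"raster values must be a 2-D grid with at least one pixel, "
                f"got shape {self.values.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def valid_mask(self) -> np.ndarray:
        """Boolean grid: True where the value is usable (not nodata, not NaN)."""
        valid = ~np.isnan(self.values.astype(float, copy=False))
        if self.nodata is not None and not math.isnan(self.nodata):
            valid &= self.values != self.nodata
        return valid

    def aligned_with(self, other: "RasterGrid") -> bool:
        return self.shape == other.shape and self.transform.isclose(other.transform)

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(values, self.transform, self.nodata, self.crs)


@dataclass
class PlotGeometry:
    """A breeding plot: polygon plus plot/variety/replicate identity."""

    plot_id: str
    variety: str
    replicate: int
    polygon: Polygon
    crs: str | None = None

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(f"plot {self.plot_id}: replicate must be >= 1")
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValidationError(
                f"plot {self.plot_id}: polygon must be simple with positive area"
            )


def _crs_geokeys(crs: str | None) -> tuple[int, ...] | None:
    if crs is None:
        return None
    ident = crs.upper().replace(" ", "")
    if not ident.startswith("EPSG:"):
        raise RasterIOError(f"only EPSG CRS identifiers are supported, got {crs!r}")
    code = int(ident.split(":", 1)[1])
    keys = [
        (_KEY_MODEL_TYPE, 0, 1, 1),
        (_KEY_RASTER_TYPE, 0, 1, 1),
        (_KEY_PROJECTED_CS_TYPE, 0, 1, code),
    ]
    flat: list[int] = [1, 1, 0, len(keys)]
    for k in keys:
        flat.extend(k)
    return tuple(flat)


def _parse_geokeys(flat: Sequence[int]) -> dict[int, int]:
    keys: dict[int, int] = {}
    n = flat[3]
    for i in range(n):
        key_id, location, count, value = flat[4 + 4 * i : 8 + 4 * i]
        if location == 0 and count == 1:
            keys[key_id] = value
    return keys


def write_raster(grid: RasterGrid, path: str | Path) -> None:
    """Write a RasterGrid as a single-band GeoTIFF (float32, or uint8 masks)."""
    t = grid.transform
    values = grid.values
    if values.dtype == np.uint8 or (
        values.dtype.kind in "iub" and values.size and values.max(initial=0) <= 255
    ):
        data = values.astype(np.uint8)
    else:
        data = values.astype(np.float32)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (t.gsd_x, t.gsd_y, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.origin_x, t.origin_y, 0.0)),
    ]
    geokeys = _crs_geokeys(grid.crs)
    if geokeys is not None:
        extratags.append((_TAG_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys))
    if grid.nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, repr(float(grid.nodata))))
    tifffile.imwrite(str(path), data, extratags=extratags)


def read_raster(path: str | Path) -> RasterGrid:
    """Read a single-band GeoTIFF into a RasterGrid.

    Rejects rotated/sheared transforms and geographic (degree-unit)
    CRSs; the pipeline operates on north-up, metre-unit products only.
    """
    path = Path(path)
    if not path.exists():
        raise RasterIOError(f"raster file not found: {path}")
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        values = page.asarray()
        if values.ndim == 3 and values.shape[2] == 1:
            values = values[:, :, 0]
        if values.ndim != 2:
            raise RasterIOError(f"{path}: expected a single-band raster")
        tags = page.tags
        if _TAG_MODEL_TRANSFORMATION in tags:
            m = tags[_TAG_MODEL_TRANSFORMATION].value
            # full affine matrix: reject any rotation/shear terms
            if abs(m[1]) > 0 or abs(m[4]) > 0:
                raise RasterIOError(
                    f"{path}: unsupported geometry (rotated or sheared transform)"
                )
            scale = (m[0], -m[5], 0.0)
            tiepoint = (0.0, 0.0, 0.0, m[3], m[7], 0.0)
        else:
            if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
                raise RasterIOError(f"{path}: missing GeoTIFF georeferencing tags")
            scale = tags[_TAG_MODEL_PIXEL_SCALE].value
            tiepoint = tags[_TAG_MODEL_TIEPOINT].value
        crs = None
        if _TAG_GEO_KEY_DIRECTORY in tags:
            keys = _parse_geokeys(tags[_TAG_GEO_KEY_DIRECTORY].value)
            model_type = keys.get(_KEY_MODEL_TYPE)
            if model_type == 2 or _KEY_GEOGRAPHIC_TYPE in keys:
                raise RasterIOError(
                    f"{path}: projected CRS required (geographic, degree-unit "
                    f"CRS found)"
                )
            if _KEY_PROJECTED_CS_TYPE in keys:
                crs = f"EPSG:{keys[_KEY_PROJECTED_CS_TYPE]}"
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
    transform = GridTransform(
        origin_x=float(tiepoint[3]),
        origin_y=float(tiepoint[4]),
        gsd_x=float(scale[0]),
        gsd_y=float(scale[1]),
    )
    return RasterGrid(values=values, transform=transform, nodata=nodata, crs=crs)


# ---------------------------------------------------------------------------
# plot polygons (GeoJSON)
# ---------------------------------------------------------------------------

_DEFAULT_ATTRS = {"plot_id": "plot_id", "variety": "variety", "replicate": "replicate"}


def read_plots(
    path: str | Path, attr_map: dict[str, str] | None = None
) -> list[PlotGeometry]:
    """Read plot polygons from a GeoJSON FeatureCollection.

    ``attr_map`` maps the canonical attribute names (``plot_id``,
    ``variety``, ``replicate``) to the property names used in the file.
    """
    path = Path(path)
    if not path.exists():
        raise RasterIOError(f"plot file not found: {path}")
    attrs = dict(_DEFAULT_ATTRS)
    if attr_map:
        attrs.update(attr_map)
    with open(path) as fh:
        doc = json.load(fh)
    features = doc.get("features", [])
    crs = None
    crs_member = doc.get("crs")
    if isinstance(crs_member, dict):
        name = crs_member.get("properties", {}).get("name", "")
        if "EPSG" in name.upper():
            crs = "EPSG:" + name.upper().rstrip("/").split("EPSG")[-1].strip(":/")
    plots: list[PlotGeometry] = []
    seen: set[str] = set()
    for feat in features:
        props = feat.get("properties", {}) or {}
        for canonical, name in attrs.items():
            if name not in props:
                raise ValidationError(
                    f"feature is missing required attribute {name!r} "
                    f"(mapped from {canonical!r})"
                )
        plot_id = str(props[attrs["plot_id"]])
        if plot_id in seen:
            raise ValidationError(f"duplicate plot_id {plot_id!r} in {path}")
        seen.add(plot_id)
        geom = shapely_shape(feat["geometry"])
        if not isinstance(geom, Polygon):
            raise ValidationError(f"plot {plot_id}: geometry must be a Polygon")
        plots.append(
            PlotGeometry(
                plot_id=plot_id,
                variety=str(props[attrs["variety"]]),
                replicate=int(props[attrs["replicate"]]),
                polygon=geom,
                crs=crs,
            )
        )
    if not plots:
        logger.warning("plot file %s contains no features", path)
    return plots


def write_plots(plots: Iterable[PlotGeometry], path: str | Path) -> None:
    """Write plot polygons as a GeoJSON FeatureCollection."""
    plots = list(plots)
    doc: dict = {"type": "FeatureCollection", "features": []}
    crs = next((p.crs for p in plots if p.crs), None)
    if crs:
        doc["crs"] = {"type": "name", "properties": {"name": f"urn:ogc:def:crs:{crs}"}}
    for p in plots:
        doc["features"].append(
            {
                "type": "Feature",
                "geometry": shapely_mapping(p.polygon),
                "properties": {
                    "plot_id": p.plot_id,
                    "variety": p.variety,
                    "replicate": p.replicate,
                },
            }
        )
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# zonal support and resampling
# ---------------------------------------------------------------------------


def polygon_pixel_mask(grid: RasterGrid, polygon: Polygon) -> np.ndarray:
    """Boolean grid of pixels whose centres fall inside ``polygon``.

    Pixel-centre-in-polygon with the boundary counted as inside on the
    south and west edges only, so zonal counts are reproducible
    bit-exactly when plot edges coincide with pixel centres.
    """
    rows, cols = grid.shape
    xs, ys = grid.transform.pixel_centers(grid.shape)
    minx, miny, maxx, maxy = polygon.bounds
    col_sel = (xs >= minx - grid.transform.gsd_x) & (xs <= maxx + grid.transform.gsd_x)
    row_sel = (ys >= miny - grid.transform.gsd_y) & (ys <= maxy + grid.transform.gsd_y)
    mask = np.zeros((rows, cols), dtype=bool)
    ci = np.where(col_sel)[0]
    ri = np.where(row_sel)[0]
    if ci.size == 0 or ri.size == 0:
        return mask
    X, Y = np.meshgrid(xs[ci], ys[ri])
    inside = shapely.contains_xy(polygon, X.ravel(), Y.ravel()).reshape(X.shape)
    on_boundary = shapely.intersects_xy(polygon, X.ravel(), Y.ravel()).reshape(X.shape)
    on_boundary &= ~inside
    if on_boundary.any():
        eps = 1e-9 * max(grid.transform.gsd_x, grid.transform.gsd_y)
        south_west = (X <= minx + eps) | (Y <= miny + eps)
        inside |= on_boundary & south_west
    mask[np.ix_(ri, ci)] = inside
    return mask


def resample_to(
    grid: RasterGrid, reference: RasterGrid, method: str = "nearest"
) -> RasterGrid:
    """Resample ``grid`` onto the transform and shape of ``reference``.

    ``nearest`` looks up the source pixel containing each reference
    pixel centre (required for masks); ``average`` takes the mean of
    the source pixel centres falling inside each reference pixel, never
    averaging nodata in.
    """
    if method not in ("nearest", "average"):
        raise ValueError(f"unknown resampling method {method!r}")
    if grid.crs is not None and reference.crs is not None and grid.crs != reference.crs:
        raise ValidationError(
            f"CRS mismatch: source {grid.crs!r} vs reference {reference.crs!r}"
        )
    if grid.aligned_with(reference):
        return grid.copy_with(grid.values.copy())

    src_t, ref_t = grid.transform, reference.transform
    out_nodata = grid.nodata if grid.nodata is not None else np.nan
    if method == "nearest":
        xs, ys = ref_t.pixel_centers(reference.shape)
        X, Y = np.meshgrid(xs, ys)
        row, col = src_t.world_to_pixel(X, Y)
        valid = (row >= 0) & (row < grid.shape[0]) & (col >= 0) & (col < grid.shape[1])
        if not valid.any():
            raise ValidationError("empty overlap between source and reference grids")
        out = np.full(reference.shape, out_nodata, dtype=float)
        out[valid] = grid.values[row[valid], col[valid]]
        if grid.values.dtype.kind in "iub" and grid.nodata is not None:
            out = out.astype(grid.values.dtype, copy=False)
        return RasterGrid(out, ref_t, grid.nodata, grid.crs)

    # average: bin source pixel centres into reference cells
    sxs, sys = src_t.pixel_centers(grid.shape)
    SX, SY = np.meshgrid(sxs, sys)
    trow, tcol = ref_t.world_to_pixel(SX, SY)
    in_ref = (
        (trow >= 0)
        & (trow < reference.shape[0])
        & (tcol >= 0)
        & (tcol < reference.shape[1])
    )
    contributing = in_ref & grid.valid_mask()
    if not in_ref.any():
        raise ValidationError("empty overlap between source and reference grids")
    flat = trow[contributing] * reference.shape[1] + tcol[contributing]
    n_cells = reference.shape[0] * reference.shape[1]
    sums = np.bincount(flat, weights=grid.values[contributing].astype(float), minlength=n_cells)
    counts = np.bincount(flat, minlength=n_cells)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = sums / counts
    out = np.full(n_cells, out_nodata, dtype=float)
    filled = counts > 0
    out[filled] = means[filled]
    return RasterGrid(out.reshape(reference.shape), ref_t, grid.nodata, grid.crs)
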