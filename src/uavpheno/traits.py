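"""Plot-level trait extraction: height, canopy volume, coverage, indices.

Per-pixel plant height is DSM altitude minus the plot's base-plane
altitude, ``H = Z - zplane``, evaluated on vegetation-mask pixels
inside the plot polygon and clipped below at zero.  Canopy volume is
the sum of per-pixel columns ``V = L * W * H`` where the pixel edge
lengths L and W both equal the ground sampling distance, so

    volume = pixel_area * n_canopy_pixels * mean_height

holds exactly by construction.  Coverage is the canopy-pixel area
fraction of the plot polygon.  Vegetation indices are per-pixel band
algebra averaged over the same masked pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .base_plane import BasePlane
from .raster_io import (
    PlotGeometry,
    RasterGrid,
    ValidationError,
    polygon_pixel_mask,
)
from .segmentation import VegetationMask

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IndexDefinition:
    """A named vegetation index as a function of reflectance bands."""

    name: str
    bands: tuple[str, ...]
    formula: Callable[..., np.ndarray]
    description: str = ""


def _ndvi(red, nir):
    return (nir - red) / (nir + red)


def _gndvi(green, nir):
    return (nir - green) / (nir + green)


def _ndre(rededge, nir):
    return (nir - rededge) / (nir + rededge)


def _clre(rededge, nir):
    return nir / rededge - 1.0


def _lci(red, rededge, nir):
    return (nir - rededge) / (nir + red)


#: the standard index set: normalised-difference and ratio indices of
#: NIR against Red / Green / RedEdge reflectance
INDEX_DEFINITIONS: dict[str, IndexDefinition] = {
    "ndvi": IndexDefinition(
        "ndvi", ("red", "nir"), _ndvi, "Normalised Difference Vegetation Index"
    ),
    "gndvi": IndexDefinition(
        "gndvi", ("green", "nir"), _gndvi, "Green NDVI (green-band variant)"
    ),
    "ndre": IndexDefinition(
        "ndre", ("rededge", "nir"), _ndre, "Normalised Difference Red Edge"
    ),
    "clre": IndexDefinition(
        "clre", ("rededge", "nir"), _clre, "Chlorophyll Index Red-Edge"
    ),
    "lci": IndexDefinition("lci", ("red", "rededge", "nir"), _lci, "Leaf Chlorophyll Index"),
}


@dataclass
class TraitRecord:
    """Traits of one plot on one date."""

    plot_id: str
    date_label: str = ""
    days_after_planting: int | None = None
    mean_height: float = 0.0
    volume: float = 0.0
    coverage: float = 0.0
    ndvi: float = float("nan")
    ndre: float = float("nan")
    clre: float = float("nan")
    lci: float = float("nan")
    n_canopy_pixels: int = 0
    no_canopy: bool = False
    variety: str | None = None
    replicate: int | None = None


@dataclass
class TraitConfig:
    """Options governing trait extraction.

    ``mask_mode="canopy"`` averages indices over segmented canopy
    pixels only; ``"plot"`` averages over every plot pixel, mimicking a
    whole-plot proximal sensor scan.  ``ndvi_variant`` selects the
    red-band NDVI (default) or the green-band GNDVI for the ``ndvi``
    column.  Negative heights (DSM below the base plane) are clipped to
    zero unless ``clip_negative_heights`` is disabled.
    """

    date_label: str = ""
    days_after_planting: int | None = None
    mask_mode: str = "canopy"
    ndvi_variant: str = "ndvi"
    clip_negative_heights: bool = True
    indices: tuple[str, ...] = ("ndvi", "ndre", "clre", "lci")


def _require_aligned(a: RasterGrid, b: RasterGrid, what: str) -> None:
    if not a.aligned_with(b):
        raise ValidationError(f"{what}: grids are not aligned (transform/shape differ)")


def height_map(
    dsm: RasterGrid,
    plane: BasePlane,
    mask: VegetationMask,
    plot: PlotGeometry,
    clip_negative: bool = True,
) -> RasterGrid:
    """Per-pixel plant height ``H = Z - zplane`` on masked plot pixels.

    Pixels outside the plot polygon or the vegetation mask are NaN
    (nodata); negative heights are clipped to zero by default.
    """
    _require_aligned(dsm, mask.grid, "height_map(dsm, mask)")
    if plane.plot_id != plot.plot_id:
        raise ValidationError(
            f"base plane belongs to plot {plane.plot_id!r}, not {plot.plot_id!r}"
        )
    select = polygon_pixel_mask(dsm, plot.polygon) & mask.canopy() & dsm.valid_mask()
    h = np.full(dsm.shape, np.nan, dtype=float)
    h[select] = dsm.values[select].astype(float) - plane.zplane
    if clip_negative:
        np.clip(h, 0.0, None, out=h)
    return RasterGrid(h, dsm.transform, nodata=None, crs=dsm.crs)


def plot_mean_height(hmap: RasterGrid) -> tuple[float, int]:
    """Mean height over canopy pixels and the pixel count.

    Returns ``(0.0, 0)`` for a plot with no canopy pixels — legitimate
    early in the season before emergence.
    """
    valid = hmap.valid_mask()
    n = int(valid.sum())
    if n == 0:
        return 0.0, 0
    return float(hmap.values[valid].mean()), n


def plot_volume(hmap: RasterGrid) -> float:
    """Canopy volume: sum of per-pixel ``gsd_x * gsd_y * H`` columns, m^3."""
    valid = hmap.valid_mask()
    if not valid.any():
        return 0.0
    return float(hmap.values[valid].sum() * hmap.transform.pixel_area)


def plot_coverage(mask: VegetationMask, plot: PlotGeometry) -> float:
    """Canopy-pixel area inside the plot divided by the polygon area."""
    inside = polygon_pixel_mask(mask.grid, plot.polygon)
    if not inside.any():
        raise ValidationError(
            f"plot {plot.plot_id}: no pixel centres fall inside the polygon"
        )
    n_canopy = int((inside & mask.canopy()).sum())
    return n_canopy * mask.grid.transform.pixel_area / plot.polygon.area


def index_map(
    bands: Mapping[str, RasterGrid], definition: IndexDefinition | str
) -> RasterGrid:
    """Evaluate a vegetation index per pixel over aligned band grids.

    Pixels where any operand is nodata, or where the formula divides by
    zero, become NaN (nodata); their count is logged.
    """
    if isinstance(definition, str):
        try:
            definition = INDEX_DEFINITIONS[definition.lower()]
        except KeyError:
            raise ValidationError(f"unknown vegetation index {definition!r}") from None
    grids = []
    for name in definition.bands:
        if name not in bands:
            raise ValidationError(
                f"index {definition.name!r} needs band {name!r}, which is missing"
            )
        grids.append(bands[name])
    ref = grids[0]
    for g in grids[1:]:
        _require_aligned(ref, g, f"index_map({definition.name})")
    valid = np.ones(ref.shape, dtype=bool)
    for g in grids:
        valid &= g.valid_mask()
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = definition.formula(*(g.values.astype(float) for g in grids))
    out = np.where(valid & np.isfinite(raw), raw, np.nan)
    n_bad = int((valid & ~np.isfinite(raw)).sum())
    if n_bad:
        logger.info("index %s: %d pixel(s) with zero denominator", definition.name, n_bad)
    return RasterGrid(out, ref.transform, nodata=None, crs=ref.crs)


def plot_index_mean(
    index_grid: RasterGrid,
    mask: VegetationMask,
    plot: PlotGeometry,
    mask_mode: str = "canopy",
) -> tuple[float, int]:
    """Mean index over the plot's canopy pixels (or all plot pixels).

    Returns ``(nan, 0)`` when the selection is empty (no canopy).
    """
    if mask_mode not in ("canopy", "plot"):
        raise ValidationError(f"unknown mask_mode {mask_mode!r}")
    _require_aligned(index_grid, mask.grid, "plot_index_mean")
    select = polygon_pixel_mask(index_grid, plot.polygon) & index_grid.valid_mask()
    if mask_mode == "canopy":
        select &= mask.canopy()
    n = int(select.sum())
    if n == 0:
        return float("nan"), 0
    return float(index_grid.values[select].mean()), n


def extract_traits(
    dsm: RasterGrid,
    bands: Mapping[str, RasterGrid],
    mask: VegetationMask,
    plots: Iterable[PlotGeometry],
    planes: Mapping[str, BasePlane],
    config: TraitConfig | None = None,
) -> list[TraitRecord]:
    """Run the full per-plot trait extraction for one acquisition date.

    A failure on one plot is logged with its plot id and does not stop
    the remaining plots.  Output order follows the input plot order, so
    reruns on identical inputs are byte-identical when serialised.
    """
    config = config or TraitConfig()
    index_grids = {}
    for name in config.indices:
        key = config.ndvi_variant if name == "ndvi" else name
        index_grids[name] = index_map(bands, key)
    records: list[TraitRecord] = []
    for plot in plots:
        if plot.plot_id not in planes:
            raise ValidationError(f"no base plane for plot {plot.plot_id!r}")
        try:
            hmap = height_map(
                dsm, planes[plot.plot_id], mask, plot,
                clip_negative=config.clip_negative_heights,
            )
            mean_h, n_canopy = plot_mean_height(hmap)
            record = TraitRecord(
                plot_id=plot.plot_id,
                date_label=config.date_label,
                days_after_planting=config.days_after_planting,
                mean_height=mean_h,
                volume=plot_volume(hmap),
                coverage=plot_coverage(mask, plot),
                n_canopy_pixels=n_canopy,
                no_canopy=n_canopy == 0,
                variety=plot.variety,
                replicate=plot.replicate,
            )
            for name, grid in index_grids.items():
                value, _ = plot_index_mean(grid, mask, plot, config.mask_mode)
                setattr(record, name, value)
            records.append(record)
        except (ValidationError, ValueError) as exc:
            logger.error(
                "plot %s, date %s: %s", plot.plot_id, config.date_label or "?", exc
            )
    return records


_COLUMNS = [
    "plot_id", "variety", "replicate", "date_label", "days_after_planting",
    "mean_height", "volume", "coverage", "ndvi", "ndre", "clre", "lci",
    "n_canopy_pixels", "no_canopy",
]


def records_to_frame(records: Iterable[TraitRecord]) -> pd.DataFrame:
    frame = pd.DataFrame([vars(r) for r in records])
    if frame.empty:
        return pd.DataFrame(columns=_COLUMNS)
    return frame[_COLUMNS]


def write_traits(records: Iterable[TraitRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)
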