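"""Vegetation masks: externally produced or index-threshold fallback.

The pipeline's contract is a binary mask aligned to the rasters it is
applied to, however the mask was produced.  A learned segmentation
(e.g. an encoder-decoder CNN run outside this package) is loaded with
:func:`load_external_mask`; :func:`threshold_mask` is a deliberately
simple index-threshold fallback for when no learned mask exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster_io import RasterGrid, ValidationError, read_raster, resample_to

MASK_NODATA = 255


@dataclass
class VegetationMask:
    """Binary vegetation mask on a reference grid.

    ``source`` records provenance: ``"external"`` for an imported mask,
    ``"threshold"`` for the index-threshold fallback (with the index
    name and threshold retained for the run manifest).
    """

    grid: RasterGrid
    source: str
    index_name: str | None = None
    threshold: float | None = None

    @property
    def values(self) -> np.ndarray:
        return self.grid.values

    def canopy(self) -> np.ndarray:
        """Boolean grid, True on vegetation pixels."""
        return (self.grid.values == 1) & self.grid.valid_mask()


def load_external_mask(
    path_or_grid: "str | RasterGrid", reference: RasterGrid, tolerance: float = 0.01
) -> VegetationMask:
    """Load a mask raster and align it (nearest-neighbour) to ``reference``.

    Values are coerced to {0, 1}: anything farther than ``tolerance``
    from an integer in {0, 1} is a validation error, since a
    vegetation mask that is not binary signals an upstream mistake.
    """
    grid = path_or_grid if isinstance(path_or_grid, RasterGrid) else read_raster(path_or_grid)
    if grid.crs is not None and reference.crs is not None and grid.crs != reference.crs:
        raise ValidationError(
            f"mask CRS {grid.crs!r} does not match reference CRS {reference.crs!r}"
        )
    if not grid.aligned_with(reference):
        grid = resample_to(grid, reference, method="nearest")
    values = grid.values.astype(float)
    valid = grid.valid_mask()
    rounded = np.rint(values)
    bad = valid & (
        (np.abs(values - rounded) > tolerance) | ~np.isin(rounded, (0.0, 1.0))
    )
    if bad.any():
        raise ValidationError(
            f"mask contains {int(bad.sum())} pixel(s) outside {{0, 1, nodata}}"
        )
    out = np.full(grid.shape, MASK_NODATA, dtype=np.uint8)
    out[valid] = rounded[valid].astype(np.uint8)
    nodata = MASK_NODATA if (~valid).any() else None
    return VegetationMask(
        grid=RasterGrid(out, grid.transform, nodata=nodata, crs=grid.crs),
        source="external",
    )


def threshold_mask(
    index_grid: RasterGrid, threshold: float, index_name: str = "ndvi"
) -> VegetationMask:
    """Mask = 1 where the index is >= threshold (inclusive), else 0.

    Nodata pixels propagate as nodata.  The inclusive comparison is a
    documented convention: ties count as vegetation, so thresholds set
    exactly at a class value behave predictably.
    """
    values = index_grid.values.astype(float)
    valid = index_grid.valid_mask()
    if not np.isfinite(values[valid]).all():
        raise ValidationError("index grid contains non-finite values outside nodata")
    out = np.full(index_grid.shape, MASK_NODATA, dtype=np.uint8)
    out[valid] = (values[valid] >= threshold).astype(np.uint8)
    nodata = MASK_NODATA if (~valid).any() else None
    return VegetationMask(
        grid=RasterGrid(out, index_grid.transform, nodata=nodata, crs=index_grid.crs),
        source="threshold",
        index_name=index_name,
        threshold=threshold,
    )
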