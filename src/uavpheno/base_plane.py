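"""Per-plot base-plane estimation from a bare-soil DSM.

Plant height is DSM altitude minus a per-plot reference altitude
``zplane`` taken at the ridge top.  The estimator collects the
bare-soil DSM values whose pixel centres fall inside the plot polygon,
sorts them, and selects the nearest-rank 90th-percentile order
statistic: low furrow values fall below the rank and sparse high noise
spikes above it, leaving the flat ridge-top altitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .raster_io import PlotGeometry, RasterGrid, ValidationError, polygon_pixel_mask


class BasePlaneError(ValueError):
    pass


@dataclass(frozen=True)
class BasePlane:
    """Reference (ridge-top) altitude of one plot, with provenance."""

    plot_id: str
    zplane: float
    n_pixels: int
    percentile: float = 0.90
    source_date: str | None = None


def nearest_rank(values: np.ndarray, percentile: float) -> float:
    """Sorted-order statistic at 1-based rank ``ceil(percentile * n)``.

    This is the "sort and select an element" percentile: the result is
    always a member of the input array, never an interpolated value.
    """
    values = np.sort(np.asarray(values, dtype=float))
    n = values.size
    if n == 0:
        raise BasePlaneError("cannot take a percentile of an empty array")
    rank = math.ceil(percentile * n)
    rank = min(max(rank, 1), n)
    return float(values[rank - 1])


def estimate_base_plane(
    dsm: RasterGrid,
    plot: PlotGeometry,
    percentile: float = 0.90,
    source_date: str | None = None,
) -> BasePlane:
    """Estimate a plot's base altitude from a bare-soil DSM."""
    if not 0.0 < percentile < 1.0:
        raise ValidationError(f"percentile must be in (0, 1), got {percentile}")
    inside = polygon_pixel_mask(dsm, plot.polygon)
    if not inside.any():
        raise BasePlaneError(
            f"plot {plot.plot_id}: no pixel centres fall inside the polygon"
        )
    usable = inside & dsm.valid_mask()
    if not usable.any():
        raise BasePlaneError(f"plot {plot.plot_id}: all pixels inside are nodata")
    values = dsm.values[usable].astype(float)
    return BasePlane(
        plot_id=plot.plot_id,
        zplane=nearest_rank(values, percentile),
        n_pixels=int(values.size),
        percentile=percentile,
        source_date=source_date,
    )


def estimate_base_planes(
    dsm: RasterGrid,
    plots: Iterable[PlotGeometry],
    percentile: float = 0.90,
    source_date: str | None = None,
) -> dict[str, BasePlane]:
    return {
        p.plot_id: estimate_base_plane(dsm, p, percentile, source_date)
        for p in plots
    }


def write_base_planes(planes: Sequence[BasePlane] | dict[str, BasePlane], path: str | Path) -> None:
    """Persist base planes as CSV for reuse across the season."""
    if isinstance(planes, dict):
        planes = list(planes.values())
    frame = pd.DataFrame(
        [
            {
                "plot_id": p.plot_id,
                "zplane": p.zplane,
                "n_pixels": p.n_pixels,
                "percentile": p.percentile,
                "source_date": p.source_date,
            }
            for p in planes
        ]
    ).sort_values("plot_id")
    frame.to_csv(path, index=False)


def read_base_planes(path: str | Path) -> dict[str, BasePlane]:
    frame = pd.read_csv(path)
    planes = {}
    for row in frame.itertuples(index=False):
        source_date = None if pd.isna(row.source_date) else str(row.source_date)
        planes[str(row.plot_id)] = BasePlane(
            plot_id=str(row.plot_id),
            zplane=float(row.zplane),
            n_pixels=int(row.n_pixels),
            percentile=float(row.percentile),
            source_date=source_date,
        )
    return planes
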