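"""Analytic potato-field scene generator with closed-form ground truth.

A scene is a continuous surface — trapezoidal soil ridges plus
parametric plant canopies sitting on the ridge tops — point-sampled at
pixel centres onto a DSM, five reflectance bands and a vegetation mask
at any ground sampling distance (GSD).  Because the surface is
analytic, per-plot mean height, canopy volume and coverage are known in
closed form, which is what makes resolution-sensitivity experiments
(the 15 m vs 30 m flight pair) testable without a real field.

The default field emulates a ridged potato trial: 4.5 x 2.25 m plots,
ridges 30 cm high at 75 cm spacing, plants at 30 cm spacing along each
ridge.  The two canonical GSDs are 1/120 m and 1/60 m (0.833 and 1.667
cm/pixel, the 15 m and 30 m flight altitudes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from shapely.geometry import Polygon

from .raster_io import GridTransform, PlotGeometry, RasterGrid

#: canonical pixel sizes, metres/pixel, for the 15 m and 30 m flights
GSD_15M: float = 1.0 / 120.0
GSD_30M: float = 1.0 / 60.0

BAND_NAMES: tuple[str, ...] = ("blue", "green", "red", "rededge", "nir")

#: typical bare-soil and healthy-leaf reflectance spectra, unitless [0, 1]
SOIL_REFLECTANCE: dict[str, float] = {
    "blue": 0.08, "green": 0.12, "red": 0.20, "rededge": 0.22, "nir": 0.25,
}
LEAF_REFLECTANCE: dict[str, float] = {
    "blue": 0.04, "green": 0.08, "red": 0.05, "rededge": 0.30, "nir": 0.55,
}

_VARIETIES = (
    "Euroviva", "Etana", "Priska", "Sorentina", "Montana",
    "Toyoshiro", "Konahime", "IrishCobbler",
)

_DEFAULT_CRS = "EPSG:32654"  # UTM 54N
_FIELD_ORIGIN = (500000.0, 4750000.0)  # west, south corner of the field


def gsd_at_altitude(
    altitude_m: float,
    reference_altitude_m: float = 15.0,
    reference_gsd: float = GSD_15M,
) -> float:
    """Pixel size at a flight altitude by proportional scaling.

    GSD grows linearly with altitude for a fixed camera, so the 30 m
    flight has twice the 15 m pixel edge (0.833 -> 1.667 cm/pixel).
    """
    if altitude_m <= 0:
        raise ValueError("altitude must be positive")
    return reference_gsd * altitude_m / reference_altitude_m


@dataclass(frozen=True)
class CanopyModel:
    """Per-plant canopy: a cuboid or hemiellipsoid on the ridge top.

    ``radius_x``/``radius_y`` are footprint half-extents (m); ``height``
    is the apex height above the ridge top (m).  The hemiellipsoid has
    height ``c * sqrt(1 - (dx/a)^2 - (dy/b)^2)`` over an elliptical
    footprint.
    """

    shape: str = "hemiellipsoid"  # or "cuboid"
    height: float = 0.45
    radius_x: float = 0.15
    radius_y: float = 0.15

    def __post_init__(self) -> None:
        if self.shape not in ("hemiellipsoid", "cuboid"):
            raise ValueError(f"unknown canopy shape {self.shape!r}")
        if min(self.height, self.radius_x, self.radius_y) <= 0:
            raise ValueError("canopy height and radii must be positive")

    @property
    def footprint_area(self) -> float:
        if self.shape == "cuboid":
            return 4.0 * self.radius_x * self.radius_y
        return math.pi * self.radius_x * self.radius_y

    @property
    def volume(self) -> float:
        if self.shape == "cuboid":
            return self.footprint_area * self.height
        return (2.0 / 3.0) * math.pi * self.radius_x * self.radius_y * self.height

    @property
    def mean_height(self) -> float:
        """Mean canopy height over the footprint (volume / footprint area)."""
        return self.volume / self.footprint_area

    def height_at(self, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
        """Canopy height at offsets (dx, dy) from the plant centre."""
        if self.shape == "cuboid":
            covered = self.covers(dx, dy)
            return np.where(covered, self.height, 0.0)
        u = (dx / self.radius_x) ** 2 + (dy / self.radius_y) ** 2
        return self.height * np.sqrt(np.clip(1.0 - u, 0.0, None))

    def covers(self, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
        """True where the canopy footprint covers the offset point.

        The cuboid footprint is half-open, ``[-r, r)`` on each axis, so
        pixel-centre sampling counts exactly ``2r/gsd`` pixels per axis
        whether the edges land on pixel boundaries or on pixel centres —
        the Riemann-exactness convention for grid-commensurate cuboids.
        """
        if self.shape == "cuboid":
            return (
                (dx >= -self.radius_x) & (dx < self.radius_x)
                & (dy >= -self.radius_y) & (dy < self.radius_y)
            )
        return (dx / self.radius_x) ** 2 + (dy / self.radius_y) ** 2 < 1.0


@dataclass
class SceneTruth:
    """Field layout, canopy model, radiometry and the implied true traits.

    Distances in metres; reflectances unitless in [0, 1].  The defaults
    reproduce the trial layout the pipeline targets: 4.5 x 2.25 m plots,
    30 cm ridges at 75 cm spacing, 30 cm plant spacing.
    """

    plot_length: float = 4.5
    plot_width: float = 2.25
    n_plots: int = 3
    plot_gap: float = 0.5
    margin: float = 0.3
    ridge_height: float = 0.30
    ridge_spacing: float = 0.75
    ridge_top_width: float = 0.25
    furrow_width: float = 0.25
    plant_spacing: float = 0.30
    canopy: CanopyModel | None = field(default_factory=CanopyModel)
    plant_layout: str = "grid"  # "grid", "single", or "explicit"
    plant_positions: Sequence[tuple[float, float]] | None = None
    soil_base: float = 10.0
    dsm_noise_sd: float = 0.01
    seed: int = 0
    soil_reflectance: dict[str, float] = field(
        default_factory=lambda: dict(SOIL_REFLECTANCE)
    )
    leaf_reflectance: dict[str, float] = field(
        default_factory=lambda: dict(LEAF_REFLECTANCE)
    )
    mix_boundary_pixels: bool = False
    crs: str = _DEFAULT_CRS

    def __post_init__(self) -> None:
        if self.plot_length <= 0 or self.plot_width <= 0 or self.n_plots < 1:
            raise ValueError("plot dimensions and count must be positive")
        ramp = self.ridge_spacing / 2 - self.ridge_top_width / 2 - self.furrow_width / 2
        if ramp <= 0:
            raise ValueError("ridge top plus furrow widths exceed the ridge spacing")
        for spectrum in (self.soil_reflectance, self.leaf_reflectance):
            for band in BAND_NAMES:
                if not 0.0 <= spectrum[band] <= 1.0:
                    raise ValueError(f"reflectance for {band!r} outside [0, 1]")
        if self.canopy is not None and self.plant_layout == "grid":
            if self.canopy.radius_x > self.plant_spacing / 2 + 1e-12:
                raise ValueError(
                    "canopy radius_x exceeds half the plant spacing: "
                    "footprints would overlap along the row"
                )
            if self.canopy.radius_y > self.ridge_spacing / 2 + 1e-12:
                raise ValueError(
                    "canopy radius_y exceeds half the ridge spacing: "
                    "footprints would overlap across ridges"
                )

    # ---- derived layout -------------------------------------------------

    @property
    def n_ridges_per_plot(self) -> int:
        return int(round(self.plot_width / self.ridge_spacing))

    @property
    def plants_per_plot(self) -> int:
        if self.canopy is None:
            return 0
        if self.plant_layout == "single":
            return 1
        if self.plant_layout == "explicit":
            return len(self.plant_positions or ())
        return self.n_ridges_per_plot * int(round(self.plot_length / self.plant_spacing))

    @property
    def field_extent(self) -> tuple[float, float]:
        """Field size (east-west, north-south) in metres, margins included."""
        ex = 2 * self.margin + self.n_plots * self.plot_length
        ex += (self.n_plots - 1) * self.plot_gap
        ey = 2 * self.margin + self.plot_width
        return ex, ey

    def plot_origin(self, k: int) -> tuple[float, float]:
        """South-west corner of plot ``k`` relative to the field origin."""
        x0 = self.margin + k * (self.plot_length + self.plot_gap)
        return x0, self.margin

    def plant_centres(self, k: int) -> list[tuple[float, float]]:
        """Plant centres of plot ``k`` relative to the field origin."""
        if self.canopy is None:
            return []
        x0, y0 = self.plot_origin(k)
        if self.plant_layout == "single":
            return [(x0 + self.plot_length / 2, y0 + self.plot_width / 2)]
        if self.plant_layout == "explicit":
            return [(x0 + px, y0 + py) for px, py in (self.plant_positions or ())]
        centres = []
        n_row = int(round(self.plot_length / self.plant_spacing))
        for r in range(self.n_ridges_per_plot):
            cy = y0 + (r + 0.5) * self.ridge_spacing
            for j in range(n_row):
                centres.append((x0 + (j + 0.5) * self.plant_spacing, cy))
        return centres

    # ---- closed-form truth ----------------------------------------------

    @property
    def true_volume(self) -> float:
        """Per-plot canopy volume, m^3 (plant volumes are non-overlapping)."""
        if self.canopy is None:
            return 0.0
        return self.plants_per_plot * self.canopy.volume

    @property
    def true_mean_height(self) -> float:
        """Mean canopy height over the canopy footprint, m."""
        if self.canopy is None or self.plants_per_plot == 0:
            return 0.0
        return self.canopy.mean_height

    @property
    def true_coverage(self) -> float:
        """Fraction of the plot area covered by canopy footprints."""
        if self.canopy is None:
            return 0.0
        cov = self.plants_per_plot * self.canopy.footprint_area
        return cov / (self.plot_length * self.plot_width)

    @property
    def ridge_top_altitude(self) -> float:
        return self.soil_base + self.ridge_height

    # ---- continuous surface ----------------------------------------------

    def soil_altitude(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Soil surface: base altitude plus a trapezoid ridge wave in y.

        Ridges run east-west; the wave has a flat top (``ridge_top_width``)
        and flat furrow floor (``furrow_width``) joined by linear ramps,
        phased so ridge crests sit at ``(r + 0.5) * ridge_spacing`` north
        of the plots' south edge.
        """
        s = self.ridge_spacing
        rel = np.mod(np.asarray(y, dtype=float) - self.margin, s)
        d = np.abs(rel - s / 2)  # distance from the nearest crest line
        half_top = self.ridge_top_width / 2
        half_furrow = self.furrow_width / 2
        ramp = s / 2 - half_top - half_furrow
        frac = np.clip((s / 2 - half_furrow - d) / ramp, 0.0, 1.0)
        return self.soil_base + self.ridge_height * frac

    def canopy_height(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Canopy height above the ridge top and the cover indicator.

        Evaluated on field-relative coordinates; vectorised over the
        regular in-plot plant grid, with an explicit loop only for the
        single / explicit layouts.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        h = np.zeros(np.broadcast_shapes(x.shape, y.shape), dtype=float)
        covered = np.zeros_like(h, dtype=bool)
        if self.canopy is None:
            return h, covered
        for k in range(self.n_plots):
            x0, y0 = self.plot_origin(k)
            in_plot = (
                (x >= x0) & (x < x0 + self.plot_length)
                & (y >= y0) & (y < y0 + self.plot_width)
            )
            if self.plant_layout == "grid":
                if not in_plot.any():
                    continue
                dx = np.mod(x - x0, self.plant_spacing) - self.plant_spacing / 2
                dy = np.mod(y - y0, self.ridge_spacing) - self.ridge_spacing / 2
                cov = self.canopy.covers(dx, dy) & in_plot
                h = np.where(cov, self.canopy.height_at(dx, dy), h)
                covered |= cov
            else:
                for cx, cy in self.plant_centres(k):
                    cov = self.canopy.covers(x - cx, y - cy)
                    h = np.where(cov, self.canopy.height_at(x - cx, y - cy), h)
                    covered |= cov
        return h, covered


@dataclass
class Scene:
    """One sampled acquisition: DSM, five bands, mask, plots, truth."""

    dsm: RasterGrid
    bands: dict[str, RasterGrid]
    mask: RasterGrid
    plots: list[PlotGeometry]
    truth: SceneTruth


def _plot_geometries(truth: SceneTruth) -> list[PlotGeometry]:
    ox, oy = _FIELD_ORIGIN
    plots = []
    for k in range(truth.n_plots):
        x0, y0 = truth.plot_origin(k)
        poly = Polygon(
            [
                (ox + x0, oy + y0),
                (ox + x0 + truth.plot_length, oy + y0),
                (ox + x0 + truth.plot_length, oy + y0 + truth.plot_width),
                (ox + x0, oy + y0 + truth.plot_width),
            ]
        )
        plots.append(
            PlotGeometry(
                plot_id=f"P{k + 1:02d}",
                variety=_VARIETIES[k % len(_VARIETIES)],
                replicate=k // len(_VARIETIES) + 1,
                polygon=poly,
                crs=truth.crs,
            )
        )
    return plots


def make_scene(truth: SceneTruth, gsd: float) -> Scene:
    """Sample the continuous field at pixel centres on a ``gsd`` grid.

    The DSM is soil + canopy + i.i.d. Gaussian elevation noise
    (``dsm_noise_sd``, seeded); each band is the leaf spectrum where the
    canopy covers the pixel centre and the soil spectrum elsewhere; the
    mask is the canopy-cover indicator.  Same truth and gsd give
    bit-identical scenes.
    """
    if gsd <= 0:
        raise ValueError("gsd must be positive")
    if gsd > min(truth.plot_length, truth.plot_width):
        raise ValueError(
            f"plot unresolvable: gsd {gsd} m exceeds the plot's short side"
        )
    ex, ey = truth.field_extent
    cols = int(math.ceil(ex / gsd - 1e-9))
    rows = int(math.ceil(ey / gsd - 1e-9))
    ox, oy = _FIELD_ORIGIN
    transform = GridTransform(
        origin_x=ox, origin_y=oy + rows * gsd, gsd_x=gsd, gsd_y=gsd
    )
    xs, ys = transform.pixel_centers((rows, cols))
    X, Y = np.meshgrid(xs - ox, ys - oy)  # field-relative coordinates

    soil = truth.soil_altitude(X, Y)
    canopy_h, covered = truth.canopy_height(X, Y)
    dsm_values = np.where(covered, truth.ridge_top_altitude + canopy_h, soil)
    if truth.dsm_noise_sd > 0:
        rng = np.random.default_rng([int(truth.seed), int(round(gsd * 1e7))])
        dsm_values = dsm_values + rng.normal(0.0, truth.dsm_noise_sd, dsm_values.shape)

    bands: dict[str, RasterGrid] = {}
    for name in BAND_NAMES:
        leaf, soil_r = truth.leaf_reflectance[name], truth.soil_reflectance[name]
        values = np.where(covered, leaf, soil_r)
        bands[name] = RasterGrid(values, transform, nodata=None, crs=truth.crs)

    mask = RasterGrid(
        covered.astype(np.uint8), transform, nodata=None, crs=truth.crs
    )
    dsm = RasterGrid(dsm_values, transform, nodata=None, crs=truth.crs)
    return Scene(dsm, bands, mask, _plot_geometries(truth), truth)


def make_bareground_scene(truth: SceneTruth, gsd: float) -> Scene:
    """The same field before emergence: ridged soil, no canopy anywhere."""
    return make_scene(replace(truth, canopy=None), gsd)


def make_height_pair(truth: SceneTruth) -> tuple[Scene, Scene]:
    """The 15 m / 30 m acquisition pair over one continuous surface.

    Both scenes sample the identical analytic field with one seed; only
    the sampling density (and the per-pixel noise draws) differ, which
    isolates the effect of ground sampling distance.
    """
    return make_scene(truth, GSD_15M), make_scene(truth, GSD_30M)
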