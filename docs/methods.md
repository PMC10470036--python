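# Methods

## The measurement problem

High-throughput phenotyping of ridged row crops (potato in particular)
uses UAV photogrammetry products — a digital surface model (DSM) of
altitudes and per-band reflectance orthomosaics — to estimate, per
breeding plot and per date: mean plant height, canopy volume, ground
coverage, and vegetation indices. A central practical question is how
the flight altitude, through its ground sampling distance (GSD),
affects the precision of these traits. `uavpheno` implements the
plot-level extraction pipeline and a synthetic-field generator that
makes the resolution question answerable with known ground truth.

## Trait definitions

**Base plane.** Each plot i gets a single horizontal reference altitude
Zplane_i, estimated from a bare-soil DSM (acquired before emergence):
collect the DSM values at pixel centres inside the plot polygon, sort
ascending, and take the element at 1-based rank ceil(0.90 · n) — the
nearest-rank 90th-percentile order statistic, with no interpolation.
On a ridged field whose flat ridge tops occupy more than 10% of the
plot area, this rank lands on the ridge-top altitude: furrow and flank
pixels fall below the rank, sparse positive noise spikes above it. The
estimator is permutation-invariant, monotone in the percentile, and
translation-equivariant. The selection runs over *all* plot pixels (not
only ridge-top pixels); the 90% rank is precisely what makes that
workable.

**Height.** H_ij = Z_ij − Zplane_i per pixel j of plot i, evaluated on
vegetation-mask pixels inside the plot polygon and clipped below at
zero (furrow pixels misclassified as canopy would otherwise contribute
negative columns early in the season). Plot height is the arithmetic
mean of H over those pixels; a plot with no canopy pixels reports 0
with a `no_canopy` flag rather than an error, since pre-emergence
plots are legitimate inputs.

**Volume.** V_ij = L · W · H_ij with L = W = GSD, summed over canopy
pixels. All lengths are metres internally; GSD values quoted in
cm/pixel are converted at the I/O boundary. By construction

    volume = pixel_area × n_canopy_pixels × mean_height

exactly — an algebraic identity the test suite asserts on every run.

**Coverage.** (count of mask=1 pixel centres inside the polygon ×
pixel area) / polygon area. No operational definition is standard in
the field-phenotyping literature beyond this area fraction; it is the
one implemented.

**Indices.** NDVI = (NIR−Red)/(NIR+Red), NDRE =
(NIR−RedEdge)/(NIR+RedEdge), CI_re = NIR/RedEdge − 1, LCI =
(NIR−RedEdge)/(NIR+Red). A green-band NDVI variant (GNDVI,
(NIR−Green)/(NIR+Green)) is selectable where a workflow defines NDVI
against the green band. Zero denominators become nodata (never ±inf)
and their count is logged. Plot means are taken over masked canopy
pixels by default; `mask_mode="plot"` averages all plot pixels, which
mimics a whole-plot proximal sensor scan.

**Zonal rule.** A pixel belongs to a plot iff its centre is inside the
polygon; centres exactly on the boundary count only on the south and
west edges. This half-open convention makes zonal counts reproducible
bit-exactly and avoids double-counting between adjacent plots.

## Segmentation

The pipeline's contract is a binary mask, however produced. Externally
produced masks (e.g. from a learned semantic-segmentation model run
elsewhere) are loaded, nearest-neighbour resampled to the reference
grid, and coerced to {0, 1} with a strict tolerance. The built-in
fallback thresholds a vegetation index with an *inclusive* (≥)
comparison — documented because ties matter for exact tests on
synthetic scenes. Thresholding is a deliberately weaker substitute for
learned segmentation on real imagery (mixed pixels, shadows); on the
generator's unmixed scenes any threshold strictly between the soil and
leaf index values recovers the true mask pixel-for-pixel, which is what
lets the rest of the pipeline be tested independently of segmentation
quality.

## The synthetic field

The generator builds a continuous analytic surface and point-samples it
at pixel centres:

- **Soil**: base altitude plus a trapezoid ridge wave (flat crest,
  default width 0.25 m; flat furrow floor 0.25 m; linear ramps) with
  30 cm amplitude and 75 cm period. A flat crest gives an unambiguous
  ridge-top altitude for the base plane — a sinusoid would not.
- **Plants**: cuboid or hemiellipsoid canopies centred on ridge crests
  at 30 cm spacing (default hemiellipsoid, apex 0.45 m, footprint
  radius 0.15 m, i.e. plants touching along the row). The DSM over a
  footprint is ridge-top + canopy height; the canopy may overhang
  flanks and furrows, as a real surface model sees only the top
  surface.
- **Plots**: 4.5 × 2.25 m rectangles (three ridges, 15 plants per
  ridge, 45 plants), in a row with 0.5 m gaps and a 0.3 m field
  margin, in a projected metre-unit CRS.
- **Bands**: pure leaf spectrum where the canopy covers the pixel
  centre, pure soil spectrum elsewhere (defaults give leaf NDVI 0.833,
  soil NDVI 0.111). A linear-mixing switch exists but is off: pure
  spectra keep mask/band consistency exact for testing.
- **Noise**: i.i.d. Gaussian elevation noise, default sd 0.01 m —
  typical of structure-from-motion DSM noise at these altitudes. Same
  seed ⇒ bit-identical scenes; the noise stream is derived from
  (seed, gsd) so the paired acquisitions draw independent noise.

Because plant volumes are closed-form ((2/3)πabc for hemiellipsoids,
4·r_x·r_y·h for cuboids) and footprints never overlap, per-plot truth
(mean height, volume, coverage) is exact.

**Sampling conventions.** Point sampling at pixel centres (not
area-weighted integration) matches how photogrammetric grid products
are interpolated, and it makes one property provable: a cuboid whose
edges are commensurate with the pixel grid is sampled *exactly*, at any
such GSD. The cuboid footprint is half-open ([−r, r) per axis) so the
count is exact whether an edge lands on a pixel boundary or on a pixel
centre. Hemiellipsoid sampling converges with error O(gsd); the error
is not monotone in gsd for a regular plant lattice (aliasing between
the footprint boundary and the grid is coherent across identical
plants), so tests assert a linear error *bound* (total footprint
perimeter × gsd), not monotone decrease.

**Canonical GSDs.** The two flight altitudes correspond to pixel edges
of 1/120 m and 1/60 m, printed as 0.833 and 1.667 cm/pixel. The
package uses the exact fractions internally (`GSD_15M`, `GSD_30M`);
rounding only happens for display. Using exact fractions is what lets
0.3 m margins, 0.75 m ridge periods and grid-aligned cuboids be
commensurate with both grids simultaneously.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: spatially correlated SfM artefacts
(doming, melt around thin structures), mixed boundary pixels and
shadowed soil in the reflectance maps, radiometric calibration error,
within-plot plant-to-plant variation, wind-blown canopy movement
between exposures, and georeferencing error between dates. Results on
synthetic scenes bound the *sampling-density* component of trait error,
not these acquisition effects.

## The resolution experiment

`gsd_experiment` recreates the two-altitude design: for each of
`n_scenes` simulated fields (canopy apex height ~ U(0.25, 0.55) m,
footprint radii ~ U(0.10, 0.15) m, leaf NIR/Red reflectance redrawn
per scene to vary NDVI), it generates the 0.833 and 1.667 cm/pixel
acquisitions of the same surface, runs the *full* pipeline on each
(base plane from a bare-soil DSM at the same GSD, NDVI-threshold mask,
trait extraction), and regresses fine vs coarse and each vs truth.
For cuboid canopies the drawn radii are multiples of the coarse pixel
edge, making the fine and coarse measurements identical — the
exact-agreement control. Comparison statistics are ordinary least
squares: R² (squared Pearson correlation), adjusted R² with the
single-predictor formula 1 − (1−R²)(n−1)/(n−2), RMSE of residuals in
trait units, and the two-sided slope p-value (values below 1e-300 are
reported as 0). R² is symmetric in the two series; slope and intercept
are not, so every report labels the predictor.

Default problem sizes — one 4.5 × 2.25 m plot per scene, 8 scene pairs
per experiment, 20 experiment replicates for the sign test — were
chosen so a full desk-scale run completes in about a minute while the
paired design still separates the resolutions cleanly (the fine flight
wins the vs-truth comparison in ≈ 90–100% of replicates).

## Numerical and design choices

- Nearest-rank (ceiling) percentile, not interpolated: "sort and
  select" yields an element of the data, which is the natural reading
  of a noise-removal step and keeps the estimator exactly
  translation-equivariant.
- One horizontal plane per plot, not a tilted fit: the base altitude is
  defined as a single scalar per plot; terrain tilt within a 4.5 m plot
  is below the noise floor this pipeline targets.
- Negative heights clipped at zero before aggregation (prevents
  noise-driven negative volumes pre-canopy); a flag disables clipping.
- CRS handling is identifier-string equality; reprojection is out of
  scope since one flight's products share a CRS. Geographic
  (degree-unit) rasters and rotated/sheared transforms are rejected
  outright rather than silently mishandled.
- Raster I/O is a thin GeoTIFF layer over `tifffile` (ModelPixelScale,
  ModelTiepoint, GeoKeyDirectory, GDAL_NODATA tags); plot vectors are
  GeoJSON. ESRI Shapefile input is not supported; convert to GeoJSON
  upstream.
- Resampling: `nearest` is pixel-centre lookup (mandatory for masks);
  `average` is the mean of contributing source-pixel centres, with
  nodata never averaged in.

## Known limitations

- The index-threshold mask fails on real imagery with mixed pixels or
  senescent canopy; use an externally produced mask there.
- Coverage can exceed 1 by a boundary-discretisation epsilon when a
  mask is coarser than the plot outline.
- The generator's plants are identical within a plot, so within-plot
  replicate spread comes only from sampling and noise.
- No multi-date growth model: time series are built by generating one
  scene per date with different canopy parameters.
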