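# uavpheno

Plot-level crop phenotyping from UAV photogrammetry products: plant
**height**, canopy **volume**, ground **coverage** and **vegetation
indices** (NDVI, NDRE, CI_re, LCI) extracted from a georeferenced
digital surface model (DSM) and per-band reflectance rasters, per
breeding plot and date. It targets ridged row crops such as potato,
where plant height must be referenced to the ridge top rather than the
ground.

The package also ships a synthetic ridged-field generator with
closed-form ground truth, built to answer a concrete acquisition
question: *how does ground sampling distance (GSD) — i.e. flight
altitude — affect trait precision?* The two canonical resolutions are
0.833 cm/pixel (15 m flight) and 1.667 cm/pixel (30 m flight).

## Method

For each plot *i*, a bare-soil DSM acquired before emergence gives a
base altitude: sort the plot's DSM values and select the element at
rank ⌈0.90·n⌉ (the nearest-rank 90th percentile), which lands on the
flat ridge top. Per-pixel plant height and canopy volume are then

    H_ij = Z_ij − Zplane_i
    V_ij = L · W · H_ij          (L = W = GSD)

evaluated on vegetation-mask pixels inside the plot polygon, with
plot height the mean of H and plot volume the sum of V. Coverage is
the canopy-pixel area fraction of the plot polygon. Indices are
per-pixel band algebra, e.g. NDVI = (NIR−Red)/(NIR+Red), averaged over
the same masked pixels. Series from two acquisitions are compared by
ordinary least squares (R², adjusted R², RMSE, slope p-value).

See `docs/methods.md` for conventions (percentile rank, pixel-in-plot
rule, clipping, the synthetic field model) and known limitations.

## Worked example

Generate a one-plot synthetic field (hemiellipsoid canopies, apex
0.45 m, footprint radius 0.15 m, 1 cm DSM noise) and run the pipeline
at the fine flight resolution:

```python
from uavpheno import (SceneTruth, GSD_15M, make_scene, make_bareground_scene,
                      estimate_base_planes, threshold_mask, index_map,
                      extract_traits, records_to_frame)

truth = SceneTruth(n_plots=1, seed=1)
scene = make_scene(truth, GSD_15M)
bare  = make_bareground_scene(truth, GSD_15M)

planes = estimate_base_planes(bare.dsm, bare.plots)
mask   = threshold_mask(index_map(scene.bands, "ndvi"), 0.4)
records = extract_traits(scene.dsm, scene.bands, mask, scene.plots, planes)
print(records_to_frame(records)[["plot_id", "mean_height", "volume",
                                 "coverage", "ndvi"]].round(4).to_string(index=False))
print(f"truth: height {truth.true_mean_height:.4f}  volume {truth.true_volume:.4f}  "
      f"coverage {truth.true_coverage:.4f}")
```

```
plot_id  mean_height  volume  coverage   ndvi
    P01       0.2944  0.9383    0.3148 0.8333
truth: height 0.3000  volume 0.9543  coverage 0.3142
```

The estimated mean height (0.2944 m) and volume (0.9383 m³) recover
the analytic truth (0.3000 m, 0.9543 m³) to within about 2% despite
the 1 cm elevation noise; the masked-mean NDVI equals the leaf NDVI
exactly because synthetic reflectance pixels are unmixed.

The same stages are available from the shell:

```sh
uavpheno synth --seed 1 --n-plots 1 --out scene/
uavpheno synth --seed 1 --n-plots 1 --bare --out bare/
uavpheno baseplane --dsm bare/dsm.tif --plots scene/plots.geojson --out planes.csv
uavpheno traits --dsm scene/dsm.tif $(for b in blue green red rededge nir; do
    echo --band=$b=scene/band_$b.tif; done) \
    --threshold 0.4 --plots scene/plots.geojson --planes planes.csv --out traits.csv
uavpheno gsd-experiment --n-scenes 8 --seed 1 --out gsdexp/
```

Every command writes a JSON manifest (effective config plus input
checksums) next to its outputs.

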