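"""Trait extraction: height, volume, coverage, indices and their identities."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from uavpheno.base_plane import BasePlane, estimate_base_planes
from uavpheno.raster_io import GridTransform, PlotGeometry, RasterGrid, ValidationError
from uavpheno.segmentation import VegetationMask, threshold_mask
from uavpheno.synthetic_field import GSD_15M, GSD_30M, make_bareground_scene, make_scene
from uavpheno.traits import (
    INDEX_DEFINITIONS,
    TraitConfig,
    extract_traits,
    height_map,
    index_map,
    plot_coverage,
    plot_index_mean,
    plot_mean_height,
    plot_volume,
    records_to_frame,
    write_traits,
)


def _grid(values, gsd=0.01, origin=(0.0, 1.0)):
    return RasterGrid(np.asarray(values, float), GridTransform(*origin, gsd, gsd))


def _full_mask(like):
    return VegetationMask(
        grid=RasterGrid(
            np.ones(like.shape, dtype=np.uint8), like.transform, crs=like.crs
        ),
        source="external",
    )


def _plot_over(grid):
    minx, miny, maxx, maxy = grid.transform.bounds(grid.shape)
    return PlotGeometry(
        "P01", "Etana", 1, Polygon([(minx, miny), (maxx, miny), (maxx, maxy), (minx, maxy)])
    )


class TestHeightMap:
    def test_height_is_dsm_minus_base_plane(self):
        dsm = _grid(np.full((4, 4), 10.45))
        plane = BasePlane("P01", zplane=10.0, n_pixels=16)
        hmap = height_map(dsm, plane, _full_mask(dsm), _plot_over(dsm))
        np.testing.assert_allclose(hmap.values[hmap.valid_mask()], 0.45)

    def test_zero_when_dsm_equals_plane(self):
        dsm = _grid(np.full((3, 3), 10.0))
        plane = BasePlane("P01", zplane=10.0, n_pixels=9)
        hmap = height_map(dsm, plane, _full_mask(dsm), _plot_over(dsm))
        np.testing.assert_allclose(hmap.values[hmap.valid_mask()], 0.0)

    def test_negative_heights_clipped_by_default(self):
        dsm = _grid(np.array([[9.8, 10.2], [10.5, 9.9]]))
        plane = BasePlane("P01", zplane=10.0, n_pixels=4)
        hmap = height_map(dsm, plane, _full_mask(dsm), _plot_over(dsm))
        assert hmap.values[hmap.valid_mask()].min() == 0.0

    def test_plane_plot_id_mismatch_rejected(self):
        dsm = _grid(np.zeros((2, 2)))
        plane = BasePlane("OTHER", zplane=10.0, n_pixels=4)
        with pytest.raises(ValidationError, match="OTHER"):
            height_map(dsm, plane, _full_mask(dsm), _plot_over(dsm))

    def test_analytic_canopy_recovered_exactly_noise_free(self, noise_free_truth):
        """Per-pixel height equals the analytic canopy height function at
        each pixel centre when there is no elevation noise."""
        scene = make_scene(noise_free_truth, 0.01)
        plane = BasePlane("P01", zplane=noise_free_truth.ridge_top_altitude, n_pixels=1)
        mask = VegetationMask(grid=scene.mask, source="external")
        hmap = height_map(scene.dsm, plane, mask, scene.plots[0])
        valid = hmap.valid_mask()
        ox, oy = 500000.0, 4750000.0
        xs, ys = scene.dsm.transform.pixel_centers(scene.dsm.shape)
        X, Y = np.meshgrid(xs - ox, ys - oy)
        analytic, _ = noise_free_truth.canopy_height(X, Y)
        np.testing.assert_allclose(hmap.values[valid], analytic[valid], atol=1e-12)


class TestMeanHeightAndVolume:
    def test_mean_of_two_pixels(self):
        hmap = _grid(np.array([[0.2, 0.6]]))
        mean, n = plot_mean_height(hmap)
        assert (mean, n) == (pytest.approx(0.4), 2)

    def test_no_canopy_returns_zero_with_empty_count(self):
        hmap = _grid(np.full((2, 2), np.nan))
        assert plot_mean_height(hmap) == (0.0, 0)
        assert plot_volume(hmap) == 0.0

    def test_single_pixel_volume(self):
        hmap = _grid(np.array([[1.0]]), gsd=0.01)
        assert plot_volume(hmap) == pytest.approx(1e-4)

    def test_cuboid_volume_exact_at_both_flight_gsds(self, aligned_cuboid_truth):
        for gsd in (GSD_15M, GSD_30M):
            scene = make_scene(aligned_cuboid_truth, gsd)
            plane = BasePlane(
                "P01", zplane=aligned_cuboid_truth.ridge_top_altitude, n_pixels=1
            )
            mask = VegetationMask(grid=scene.mask, source="external")
            hmap = height_map(scene.dsm, plane, mask, scene.plots[0])
            mean, _ = plot_mean_height(hmap)
            assert mean == pytest.approx(0.4, rel=1e-12)
            assert plot_volume(hmap) == pytest.approx(0.24, rel=1e-12)

    def test_hemiellipsoid_error_shrinks_as_gsd_halves(self, noise_free_truth):
        errors = {}
        for gsd in (GSD_15M, GSD_30M):
            scene = make_scene(noise_free_truth, gsd)
            plane = BasePlane(
                "P01", zplane=noise_free_truth.ridge_top_altitude, n_pixels=1
            )
            mask = VegetationMask(grid=scene.mask, source="external")
            hmap = height_map(scene.dsm, plane, mask, scene.plots[0])
            errors[gsd] = abs(plot_volume(hmap) - noise_free_truth.true_volume)
        assert errors[GSD_15M] < errors[GSD_30M]


class TestCoverage:
    def test_full_and_empty_masks(self, fine_scene):
        ref = fine_scene.mask
        plot = fine_scene.plots[0]
        full = VegetationMask(
            grid=RasterGrid(np.ones(ref.shape, np.uint8), ref.transform, crs=ref.crs),
            source="external",
        )
        empty = VegetationMask(
            grid=RasterGrid(np.zeros(ref.shape, np.uint8), ref.transform, crs=ref.crs),
            source="external",
        )
        assert plot_coverage(full, plot) == pytest.approx(1.0, abs=0.01)
        assert plot_coverage(empty, plot) == 0.0

    def test_matches_generator_truth_within_boundary_layer(self, fine_scene):
        truth = fine_scene.truth
        mask = VegetationMask(grid=fine_scene.mask, source="external")
        cov = plot_coverage(mask, fine_scene.plots[0])
        gsd = fine_scene.mask.transform.gsd_x
        c = truth.canopy
        boundary_area = (
            truth.plants_per_plot * np.pi * (c.radius_x + c.radius_y) * gsd
        ) / (truth.plot_length * truth.plot_width)
        assert abs(cov - truth.true_coverage) <= boundary_area


class TestIndices:
    def test_symmetry_zeros(self):
        bands = {
            "red": _grid(np.full((2, 2), 0.3)),
            "nir": _grid(np.full((2, 2), 0.3)),
            "rededge": _grid(np.full((2, 2), 0.3)),
        }
        assert np.all(index_map(bands, "ndvi").values == 0.0)
        assert np.all(index_map(bands, "ndre").values == 0.0)
        assert np.all(index_map(bands, "clre").values == 0.0)

    def test_clre_ratio_arithmetic(self):
        bands = {
            "rededge": _grid(np.full((1, 1), 0.4)),
            "nir": _grid(np.full((1, 1), 0.8)),
        }
        assert index_map(bands, "clre").values[0, 0] == pytest.approx(1.0)

    def test_all_formulas_against_scalar_oracle(self):
        rng = np.random.default_rng(8)
        bands = {
            name: _grid(rng.uniform(0.01, 1.0, (5, 5)))
            for name in ("blue", "green", "red", "rededge", "nir")
        }
        oracles = {
            "ndvi": lambda p: (p["nir"] - p["red"]) / (p["nir"] + p["red"]),
            "gndvi": lambda p: (p["nir"] - p["green"]) / (p["nir"] + p["green"]),
            "ndre": lambda p: (p["nir"] - p["rededge"]) / (p["nir"] + p["rededge"]),
            "clre": lambda p: p["nir"] / p["rededge"] - 1.0,
            "lci": lambda p: (p["nir"] - p["rededge"]) / (p["nir"] + p["red"]),
        }
        for name, oracle in oracles.items():
            grid = index_map(bands, name)
            for i in range(5):
                for j in range(5):
                    pixel = {b: bands[b].values[i, j] for b in bands}
                    assert grid.values[i, j] == pytest.approx(oracle(pixel), rel=1e-12)

    def test_normalised_indices_bounded(self):
        rng = np.random.default_rng(1)
        bands = {
            name: _grid(rng.uniform(0.0, 1.0, (6, 6)))
            for name in ("green", "red", "rededge", "nir")
        }
        for name in ("ndvi", "gndvi", "ndre"):
            values = index_map(bands, name).values
            finite = np.isfinite(values)
            assert np.all(values[finite] >= -1.0) and np.all(values[finite] <= 1.0)
        clre = index_map(bands, "clre").values
        assert np.all(clre[np.isfinite(clre)] >= -1.0)

    def test_zero_denominator_becomes_nodata(self):
        bands = {"red": _grid(np.array([[0.0]])), "nir": _grid(np.array([[0.0]]))}
        assert np.isnan(index_map(bands, "ndvi").values[0, 0])

    def test_missing_band_named(self):
        with pytest.raises(ValidationError, match="nir"):
            index_map({"red": _grid(np.zeros((2, 2)))}, "ndvi")


class TestIndexMean:
    def test_uniform_index_any_mask(self):
        grid = _grid(np.full((4, 4), 0.8))
        mask = _full_mask(grid)
        value, n = plot_index_mean(grid, mask, _plot_over(grid))
        assert value == pytest.approx(0.8)
        assert n == 16

    def test_canopy_mean_excludes_soil_exactly(self, fine_scene):
        ndvi = index_map(fine_scene.bands, "ndvi")
        mask = VegetationMask(grid=fine_scene.mask, source="external")
        value, _ = plot_index_mean(ndvi, mask, fine_scene.plots[0])
        leaf = fine_scene.truth.leaf_reflectance
        expected = (leaf["nir"] - leaf["red"]) / (leaf["nir"] + leaf["red"])
        assert value == pytest.approx(expected, abs=1e-12)

    def test_gsd_insensitivity_of_masked_ndvi(self, noise_free_truth):
        """The same field sampled at the two flight GSDs gives identical
        masked-mean NDVI: reflectance pixels are unmixed."""
        values = {}
        for gsd in (GSD_15M, GSD_30M):
            scene = make_scene(noise_free_truth, gsd)
            ndvi = index_map(scene.bands, "ndvi")
            mask = VegetationMask(grid=scene.mask, source="external")
            values[gsd], _ = plot_index_mean(ndvi, mask, scene.plots[0])
        assert abs(values[GSD_15M] - values[GSD_30M]) < 1e-12

    def test_plot_mode_averages_all_plot_pixels(self, fine_scene):
        ndvi = index_map(fine_scene.bands, "ndvi")
        mask = VegetationMask(grid=fine_scene.mask, source="external")
        canopy_mean, _ = plot_index_mean(ndvi, mask, fine_scene.plots[0], "canopy")
        plot_mean, n = plot_index_mean(ndvi, mask, fine_scene.plots[0], "plot")
        assert plot_mean < canopy_mean  # soil pixels pull the mean down
        assert n > 0


class TestExtractTraits:
    def _run(self, truth, gsd, config=None):
        scene = make_scene(truth, gsd)
        bare = make_bareground_scene(truth, gsd)
        planes = estimate_base_planes(bare.dsm, bare.plots)
        mask = threshold_mask(index_map(scene.bands, "ndvi"), 0.4)
        return scene, extract_traits(
            scene.dsm, scene.bands, mask, scene.plots, planes, config
        )

    def test_three_plot_scene_recovers_truth(self, noise_free_truth):
        from dataclasses import replace

        truth = replace(noise_free_truth, n_plots=3)
        scene, records = self._run(truth, GSD_15M)
        assert len(records) == 3
        for r in records:
            assert r.mean_height == pytest.approx(truth.true_mean_height, rel=0.01)
            assert r.volume == pytest.approx(truth.true_volume, rel=0.01)
            assert r.coverage == pytest.approx(truth.true_coverage, rel=0.05)
            assert not r.no_canopy

    def test_volume_identity_links_the_traits(self, noise_free_truth):
        """volume == pixel_area * n_canopy_pixels * mean_height, exactly."""
        for gsd in (GSD_15M, GSD_30M):
            scene, records = self._run(noise_free_truth, gsd)
            area = scene.dsm.transform.pixel_area
            for r in records:
                assert r.volume == pytest.approx(
                    area * r.n_canopy_pixels * r.mean_height, rel=1e-12
                )

    def test_dsm_translation_invariance(self, noise_free_truth):
        """Shifting all altitudes by a constant (with planes re-estimated
        on the shifted bare-soil DSM) leaves heights unchanged."""
        from dataclasses import replace

        _, records = self._run(noise_free_truth, GSD_30M)
        shifted = replace(noise_free_truth, soil_base=noise_free_truth.soil_base + 7.3)
        _, shifted_records = self._run(shifted, GSD_30M)
        assert shifted_records[0].mean_height == pytest.approx(
            records[0].mean_height, abs=1e-9
        )
        assert shifted_records[0].volume == pytest.approx(records[0].volume, abs=1e-9)

    def test_empty_mask_flags_no_canopy(self, fine_bare, noise_free_truth):
        planes = estimate_base_planes(fine_bare.dsm, fine_bare.plots)
        mask = threshold_mask(index_map(fine_bare.bands, "ndvi"), 0.4)
        records = extract_traits(
            fine_bare.dsm, fine_bare.bands, mask, fine_bare.plots, planes
        )
        assert all(r.no_canopy for r in records)
        assert all(r.volume == 0.0 for r in records)
        assert all(np.isnan(r.ndvi) for r in records)

    def test_rerun_is_byte_identical(self, tmp_path, noise_free_truth):
        _, records_a = self._run(noise_free_truth, GSD_30M)
        _, records_b = self._run(noise_free_truth, GSD_30M)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        write_traits(records_a, a)
        write_traits(records_b, b)
        assert a.read_bytes() == b.read_bytes()

    def test_frame_columns_stable(self, noise_free_truth):
        _, records = self._run(noise_free_truth, GSD_30M)
        frame = records_to_frame(records)
        assert list(frame.columns[:5]) == [
            "plot_id", "variety", "replicate", "date_label", "days_after_planting",
        ]
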