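"""Statistical comparison of trait series and the GSD simulation study.

Trait series from two acquisitions (fine vs coarse GSD, or sensor vs
manual) are compared by ordinary least squares: R^2 (squared Pearson
correlation), adjusted R^2 for the single-predictor model, RMSE of the
residuals in the trait's unit, and the two-sided p-value of the slope.
Per-variety replicate spread is the sample standard deviation.

:func:`gsd_experiment` recreates the two-altitude flight design in
simulation: paired synthetic acquisitions of the same fields at
0.833 and 1.667 cm/pixel, traits extracted through the full pipeline,
then each resolution regressed against the analytic truth and against
the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .base_plane import estimate_base_planes
from .segmentation import threshold_mask
from .synthetic_field import (
    GSD_15M,
    GSD_30M,
    CanopyModel,
    Scene,
    SceneTruth,
    make_bareground_scene,
    make_scene,
)
from .traits import TraitConfig, extract_traits, index_map, records_to_frame


class DegenerateInputError(ValueError):
    pass


@dataclass(frozen=True)
class ComparisonStats:
    """OLS summary of y regressed on x (the predictor is x)."""

    n: int
    slope: float
    intercept: float
    r2: float
    adjusted_r2: float
    rmse: float
    p_value: float
    predictor: str = "x"
    response: str = "y"


def paired_regression(
    x: np.ndarray, y: np.ndarray, predictor: str = "x", response: str = "y"
) -> ComparisonStats:
    """Ordinary least squares of ``y`` on ``x`` with the usual summaries.

    ``adjusted_r2 = 1 - (1 - r2) (n - 1) / (n - 2)`` for the one-
    predictor model; RMSE is the root mean squared residual.  Slope
    p-values below 1e-300 are reported as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"series length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise DegenerateInputError(f"need at least 3 paired observations, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("degenerate predictor: x is constant")
    result = stats.linregress(x, y)
    residuals = y - (result.slope * x + result.intercept)
    rmse = float(np.sqrt(np.mean(residuals**2)))
    r2 = float(result.rvalue**2)
    adjusted = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    p = float(result.pvalue)
    if p < 1e-300:
        p = 0.0
    return ComparisonStats(
        n=n,
        slope=float(result.slope),
        intercept=float(result.intercept),
        r2=r2,
        adjusted_r2=float(adjusted),
        rmse=rmse,
        p_value=p,
        predictor=predictor,
        response=response,
    )


def replicate_sd(values: np.ndarray) -> float:
    """Sample standard deviation (n-1 denominator) of replicate traits."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DegenerateInputError("replicate sd needs at least 2 values")
    if np.ptp(values) == 0:
        return 0.0  # avoid rounding residue from the mean subtraction
    return float(np.std(values, ddof=1))


# ---------------------------------------------------------------------------
# the two-altitude simulation experiment
# ---------------------------------------------------------------------------

_EXPERIMENT_TRAITS = ("mean_height", "volume", "coverage", "ndvi")


@dataclass
class GsdExperimentReport:
    """Per-trait regressions from paired fine/coarse synthetic flights."""

    n_scenes: int
    seed: int
    observations: pd.DataFrame
    fine_vs_coarse: dict[str, ComparisonStats] = field(default_factory=dict)
    fine_vs_truth: dict[str, ComparisonStats] = field(default_factory=dict)
    coarse_vs_truth: dict[str, ComparisonStats] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for label, stats_map in (
            ("fine_vs_coarse", self.fine_vs_coarse),
            ("fine_vs_truth", self.fine_vs_truth),
            ("coarse_vs_truth", self.coarse_vs_truth),
        ):
            for trait, cs in stats_map.items():
                rows.append(
                    {
                        "comparison": label,
                        "trait": trait,
                        "n": cs.n,
                        "slope": cs.slope,
                        "intercept": cs.intercept,
                        "r2": cs.r2,
                        "adjusted_r2": cs.adjusted_r2,
                        "rmse": cs.rmse,
                        "p_value": cs.p_value,
                    }
                )
        return pd.DataFrame(rows)


def pipeline_traits_for_scene(
    scene: Scene,
    bare: Scene,
    config: TraitConfig | None = None,
    ndvi_threshold: float = 0.4,
) -> pd.DataFrame:
    """Run the full pipeline (base plane, mask, traits) on one scene.

    The mask comes from NDVI thresholding of the scene's own bands so
    the experiment exercises the segmentation stage, not the
    generator's truth mask.
    """
    planes = estimate_base_planes(bare.dsm, bare.plots)
    ndvi = index_map(scene.bands, "ndvi")
    mask = threshold_mask(ndvi, ndvi_threshold)
    records = extract_traits(
        scene.dsm, scene.bands, mask, scene.plots, planes, config
    )
    return records_to_frame(records)


def _vary_scene(base: SceneTruth, rng: np.random.Generator, seed: int) -> SceneTruth:
    """Draw one scene's canopy and leaf spectrum, emulating the spread
    across varieties and acquisition dates."""
    shape = base.canopy.shape if base.canopy is not None else "hemiellipsoid"
    if shape == "cuboid":
        # cuboid scenes are the exact-agreement control: keep footprints
        # commensurate with both flight grids (radii in multiples of the
        # coarse pixel edge)
        radius_x = float(rng.integers(6, 10)) * GSD_30M
        radius_y = float(rng.integers(6, 10)) * GSD_30M
    else:
        radius_x = float(rng.uniform(0.10, 0.15))
        radius_y = float(rng.uniform(0.10, 0.15))
    canopy = CanopyModel(
        shape=shape,
        height=float(rng.uniform(0.25, 0.55)),
        radius_x=radius_x,
        radius_y=radius_y,
    )
    leaf = dict(base.leaf_reflectance)
    leaf["nir"] = float(rng.uniform(0.45, 0.60))
    leaf["red"] = float(rng.uniform(0.04, 0.08))
    return replace(base, canopy=canopy, leaf_reflectance=leaf, seed=seed)


def gsd_experiment(
    truth: SceneTruth,
    n_scenes: int = 8,
    seed: int = 0,
    traits: tuple[str, ...] = _EXPERIMENT_TRAITS,
) -> GsdExperimentReport:
    """Paired fine/coarse acquisitions of ``n_scenes`` simulated fields.

    Each scene redraws the canopy model (height and footprint radii)
    from the seeded generator, producing the across-scene trait spread
    the regressions need; all other field parameters come from
    ``truth``.  Per plot and scene the report holds the fine-GSD
    estimate, coarse-GSD estimate and analytic truth of each trait.
    """
    if n_scenes < 3:
        raise DegenerateInputError("need at least 3 scenes for the regressions")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_scenes):
        scene_truth = _vary_scene(truth, rng, seed=int(rng.integers(2**31 - 1)))
        fine = make_scene(scene_truth, GSD_15M)
        coarse = make_scene(scene_truth, GSD_30M)
        bare_fine = make_bareground_scene(scene_truth, GSD_15M)
        bare_coarse = make_bareground_scene(scene_truth, GSD_30M)
        frames = {
            "fine": pipeline_traits_for_scene(fine, bare_fine),
            "coarse": pipeline_traits_for_scene(coarse, bare_coarse),
        }
        truths = {
            "mean_height": scene_truth.true_mean_height,
            "volume": scene_truth.true_volume,
            "coverage": scene_truth.true_coverage,
            "ndvi": _true_ndvi(scene_truth),
        }
        for plot_id in frames["fine"]["plot_id"]:
            row = {"scene": s, "plot_id": plot_id}
            for trait in traits:
                for level, frame in frames.items():
                    value = frame.loc[frame["plot_id"] == plot_id, trait].iloc[0]
                    row[f"{trait}_{level}"] = float(value)
                row[f"{trait}_true"] = truths[trait]
            rows.append(row)
    observations = pd.DataFrame(rows)

    report = GsdExperimentReport(n_scenes=n_scenes, seed=seed, observations=observations)
    for trait in traits:
        f = observations[f"{trait}_fine"].to_numpy()
        c = observations[f"{trait}_coarse"].to_numpy()
        t = observations[f"{trait}_true"].to_numpy()
        report.fine_vs_coarse[trait] = paired_regression(
            f, c, predictor=f"{trait}@0.833cm", response=f"{trait}@1.667cm"
        )
        report.fine_vs_truth[trait] = paired_regression(
            t, f, predictor=f"{trait}_true", response=f"{trait}@0.833cm"
        )
        report.coarse_vs_truth[trait] = paired_regression(
            t, c, predictor=f"{trait}_true", response=f"{trait}@1.667cm"
        )
    return report


def _true_ndvi(truth: SceneTruth) -> float:
    leaf = truth.leaf_reflectance
    return (leaf["nir"] - leaf["red"]) / (leaf["nir"] + leaf["red"])
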