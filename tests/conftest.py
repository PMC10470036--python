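import pytest
from hypothesis import HealthCheck, settings

from uavpheno import CanopyModel, SceneTruth, make_bareground_scene, make_scene
from uavpheno.synthetic_field import GSD_15M

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def noise_free_truth() -> SceneTruth:
    """One-plot field, default hemiellipsoid canopies, no elevation noise."""
    return SceneTruth(n_plots=1, dsm_noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def fine_scene(noise_free_truth):
    return make_scene(noise_free_truth, GSD_15M)


@pytest.fixture(scope="session")
def fine_bare(noise_free_truth):
    return make_bareground_scene(noise_free_truth, GSD_15M)


@pytest.fixture(scope="session")
def aligned_cuboid_truth() -> SceneTruth:
    """A single cuboid canopy whose edges lie on pixel boundaries of both
    the 0.833 and 1.667 cm grids (footprint 1.0 x 0.6 m, height 0.4 m)."""
    return SceneTruth(
        n_plots=1,
        dsm_noise_sd=0.0,
        seed=0,
        plant_layout="explicit",
        plant_positions=[(2.25, 1.2)],
        canopy=CanopyModel(shape="cuboid", height=0.4, radius_x=0.5, radius_y=0.3),
    )
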