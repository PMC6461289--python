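import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import voxelgeom as vg

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ellipsoid():
    """The study's reference object (164.9 mm^3)."""
    return vg.default_ellipsoid()


@pytest.fixture(scope="session")
def small_ellipsoid():
    """Half-scale ellipsoid for fast unit tests in a 12 mm FoV."""
    return vg.Ellipsoid((1.35, 1.35, 2.7))


@pytest.fixture(scope="session")
def small_fov():
    return (12.0, 12.0, 12.0)


@pytest.fixture(scope="session")
def small_design(small_ellipsoid, small_fov):
    """Desk-scale factorial design used across experiment tests."""
    return vg.ExperimentDesign(
        n_variants=2,
        orientations=("parallel", "orthogonal"),
        in_plane_sizes=(0.5, 1.0),
        thickness_factors=(1.0, 1.2),
        fov=small_fov,
        ellipsoid=small_ellipsoid,
        bounds=vg.RigidBounds(translation=(-1.0, 1.0), rotation=(-8.0, 8.0)),
        master_seed=7,
        reference_in_plane=0.1,
    )


@pytest.fixture(scope="session")
def small_records(small_design):
    """Trial records of the desk-scale design under all three raters."""
    return vg.run_design(small_design, vg.default_raters(), reference_cache={})


def random_mask(grid, density, seed):
    rng = np.random.default_rng(seed)
    return vg.LabelMask(rng.random(grid.matrix_dims) < density, grid)
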