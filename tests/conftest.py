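import numpy as np
import pytest

from fltseg import (
    builtin_schedules,
    default_phantom_spec,
    generate_phantom,
    true_class_set,
)
from fltseg.phantom import PhantomSpec, Shape, default_tissue_models


@pytest.fixture(scope="session")
def schedules():
    return builtin_schedules()


@pytest.fixture(scope="session")
def noiseless_spec():
    return default_phantom_spec(noise_level=0.0, seed=0)


@pytest.fixture(scope="session")
def noiseless_phantom(noiseless_spec):
    return generate_phantom(noiseless_spec)


@pytest.fixture(scope="session")
def matched_classes(noiseless_spec):
    """Kinetic classes whose means equal the phantom's true kinetics."""
    return true_class_set(noiseless_spec)


def small_phantom_spec(
    noise_level: float,
    seed: int = 0,
    grid_shape=(20, 20, 10),
    spacing_mm=(4.0, 4.0, 4.0),
    schedule=None,
) -> PhantomSpec:
    """A compact thorax layout fitting an 80 x 80 x 40 mm grid."""
    if schedule is None:
        schedule = builtin_schedules()["vumc_trt_39"]
    organs = [
        ("heart", Shape("sphere", (22.0, 56.0, 20.0), (9.0, 9.0, 9.0))),
        ("liver", Shape("sphere", (58.0, 56.0, 20.0), (10.0, 10.0, 10.0))),
        ("vertebrae", Shape("box", (40.0, 72.0, 20.0), (5.0, 6.0, 18.0))),
        ("soft_tissue", Shape("box", (40.0, 8.0, 20.0), (30.0, 5.0, 18.0))),
    ]
    lesions = [
        ("lesion_a", Shape("sphere", (22.0, 26.0, 20.0), (7.0, 7.0, 7.0))),
        ("lesion_b", Shape("sphere", (58.0, 26.0, 20.0), (5.0, 5.0, 5.0))),
    ]
    return PhantomSpec(
        grid_shape=grid_shape,
        spacing_mm=spacing_mm,
        schedule=schedule,
        tissues=default_tissue_models(),
        organs=organs,
        lesions=lesions,
        noise_level=noise_level,
        seed=seed,
    )


@pytest.fixture()
def small_spec_factory():
    return small_phantom_spec


def sphere_image(
    grid=(48, 48, 48),
    spacing=(2.0, 2.0, 2.0),
    radius_mm=10.0,
    value=4.0,
    background=0.0,
    center_mm=None,
):
    """Noiseless hot sphere in uniform background (voxel-centre convention)."""
    if center_mm is None:
        center_mm = tuple(n * s / 2.0 for n, s in zip(grid, spacing))
    coords = np.meshgrid(
        *[(np.arange(n) + 0.5) * s for n, s in zip(grid, spacing)], indexing="ij"
    )
    d2 = sum((c - c0) ** 2 for c, c0 in zip(coords, center_mm))
    img = np.full(grid, float(background))
    img[d2 <= radius_mm**2] = float(value)
    return img, center_mm
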