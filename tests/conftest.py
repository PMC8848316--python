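import numpy as np
import pytest

from phenograd.imaging import PlantMask
from phenograd.synthetic import (
    GradientConfig,
    LayoutConfig,
    build_layout,
    build_light_map,
    default_morphotypes,
    render_scene,
)
from phenograd.synthetic.light import LightPoint


def mask_of(arr, calibration=1.0, view="side"):
    return PlantMask(pixels=np.asarray(arr, dtype=bool), calibration=calibration,
                     view=view)


def disk_mask(radius, calibration=1.0, pad=6):
    from skimage.draw import disk

    n = 2 * radius + 2 * pad
    m = np.zeros((n, n), dtype=bool)
    rr, cc = disk((n // 2, n // 2), radius)
    m[rr, cc] = True
    return mask_of(m, calibration)


def random_blob_mask(rng, size=64, n_blobs=4):
    """Union of random ellipses: irregular but plant-ish test region."""
    from skimage.draw import ellipse

    m = np.zeros((size, size), dtype=bool)
    for _ in range(n_blobs):
        r, c = rng.uniform(size * 0.25, size * 0.75, 2)
        a, b = rng.uniform(3, size * 0.2, 2)
        rot = rng.uniform(0, np.pi)
        rr, cc = ellipse(r, c, a, b, rotation=rot, shape=m.shape)
        m[rr, cc] = True
    if m.sum() < 4:
        m[size // 2: size // 2 + 3, size // 2: size // 2 + 2] = True
    return m


@pytest.fixture(scope="session")
def morphotypes():
    return default_morphotypes()


@pytest.fixture(scope="session")
def small_layout():
    return build_layout(LayoutConfig(species_rows={"caulescent": 3}), seed=11)


@pytest.fixture(scope="session")
def small_light(small_layout):
    return build_light_map(small_layout, GradientConfig(), seed=12)


@pytest.fixture(scope="session")
def caulescent_scene(morphotypes):
    lp = LightPoint("A:00:05", 48.0, 12.0, 4.0, 120.0)
    return render_scene(morphotypes["caulescent"], lp, day=21, seed=101)
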