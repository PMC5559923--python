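import numpy as np
import pytest

from cgli import EvolveParams, PhantomSpec, make_phantom
from cgli.cli import center_box_mask


@pytest.fixture(scope="session")
def disk_phantom():
    """Noise-free two-phase disk with its generative truth and FOV."""
    spec = PhantomSpec("two_phase_disk", size=(48, 48))
    return make_phantom(spec)


@pytest.fixture(scope="session")
def disk_segmentation(disk_phantom):
    from cgli import segment

    img, truth, fov = disk_phantom
    result = segment(img, center_box_mask(img.shape), EvolveParams())
    return result, truth, fov


def random_image_and_phi(rng, shape=(8, 8)):
    """A random test instance: image in [0,1], random ±1 level-set field."""
    img = rng.random(shape)
    phi = np.where(rng.random(shape) < 0.5, -1.0, 1.0)
    if (phi > 0).all() or (phi < 0).all():
        phi[0, 0] *= -1.0
    return img, phi
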