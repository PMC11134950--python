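import numpy as np
import pytest

import collagenscore as cs
from collagenscore.network import Skeleton, detect_crosslinks, extract_fiber_network


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free scene of 15 well-separated straight-ish fibers."""
    spec = cs.FiberSpec(n_fibers=15, crossing_allowed=False, noise_sd=0,
                        waviness=0.0, length_mean=100, length_sd=10,
                        width_mean=5, width_sd=0.5, orientation_kappa=2,
                        seed=3, shape=(256, 256))
    image, truth = cs.generate_fiber_image(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def clean_network(clean_scene):
    _, image, truth = clean_scene
    net, skel = cs.extract_network(truth.true_mask)
    return net, skel


def network_from_pixels(pixels, shape=(64, 64), **kwargs):
    """Build a FiberNetwork directly from hand-placed skeleton pixels."""
    mask = np.zeros(shape, dtype=bool)
    for r, c in pixels:
        mask[r, c] = True
    skel = Skeleton(mask, np.where(mask, 1.0, 0.0))
    kwargs.setdefault("min_fiber_length", 0)
    kwargs.setdefault("spur_px", 0)
    net = extract_fiber_network(skel, **kwargs)
    return detect_crosslinks(net)


@pytest.fixture
def x_network():
    """Two diagonal strokes crossing at ~90 degrees."""
    pix = [(i, i) for i in range(10, 31)] + \
          [(i, 40 - i) for i in range(10, 31)]
    return network_from_pixels(pix)


@pytest.fixture
def grid_network():
    """3 horizontal x 3 vertical straight fibers."""
    pix = {(r, c) for r in (10, 30, 50) for c in range(5, 60)} | \
          {(r, c) for c in (10, 30, 50) for r in range(5, 60)}
    return network_from_pixels(sorted(pix))
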