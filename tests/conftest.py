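"""Shared fixtures: all test volumes are generated programmatically."""

import numpy as np
import pytest

from fibromorph import BinaryVolume
from fibromorph.phantoms import FibrePhantomSpec, generate_fibre_phantom


def random_binary_volume(rng, shape, p=0.5):
    """Random two-phase volume guaranteed to contain both phases."""
    while True:
        g = (rng.random(shape) < p).astype(np.uint8)
        if g.any() and not g.all():
            return BinaryVolume(g, 1.0)


@pytest.fixture(scope="session")
def layered_phantom():
    """Default laminar fibre phantom (uniform azimuths, zero polar jitter)."""
    spec = FibrePhantomSpec(seed=11)
    volume, truth = generate_fibre_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def layered_skeleton(layered_phantom):
    from fibromorph import extract_skeleton

    _, volume, _ = layered_phantom
    return extract_skeleton(volume)
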