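import numpy as np
import pytest

from octapvd import (DiscEllipse, ScanGrid, SceneConfig, apply_exclusions,
                     build_ring_roi, generate_angiogram, quantify, sectorize)


@pytest.fixture(scope="session")
def circular_setup():
    """Factory for a centred circular-disc ring geometry with no exclusions.

    Returns (grid, ellipse, ring, sectors, measured) for a given grid size;
    results are cached per size because the EDT-based ring is the slow part.
    """
    cache = {}

    def build(n=128, radius_um=900.0, width_um=750.0, laterality="OD"):
        key = (n, radius_um, width_um, laterality)
        if key not in cache:
            grid = ScanGrid(n, n, laterality=laterality)
            ellipse = DiscEllipse((n - 1) / 2.0, (n - 1) / 2.0,
                                  radius_um, radius_um)
            ring = build_ring_roi(ellipse, grid, width_um=width_um)
            sectors = sectorize(ring, ellipse, grid)
            measured = apply_exclusions(ring, None, grid)
            cache[key] = (grid, ellipse, ring, sectors, measured)
        return cache[key]

    return build


@pytest.fixture(scope="session")
def scene_noise_free():
    """Full-resolution noise-free synthetic scene (default sector targets)."""
    config = SceneConfig(seed=5, speckle_shape=None)
    angiogram, truth = generate_angiogram(config)
    return config, angiogram, truth


@pytest.fixture(scope="session")
def quantified_noise_free(scene_noise_free):
    _, angiogram, truth = scene_noise_free
    return truth, quantify(angiogram, truth.disc)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
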