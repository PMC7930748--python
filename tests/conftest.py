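import math

import numpy as np
import pytest

import epimorph as em


def regular_polygon(n: int, side: float = 1.0, rotation: float = 0.0) -> np.ndarray:
    """Vertices of a regular n-gon with the given side length."""
    radius = side / (2.0 * math.sin(math.pi / n))
    angles = 2.0 * math.pi * np.arange(n) / n + rotation
    return radius * np.column_stack([np.cos(angles), np.sin(angles)])


def random_star_polygon(rng: np.random.Generator, n_min: int = 4, n_max: int = 12) -> np.ndarray:
    """A random simple (star-shaped) polygon around the origin."""
    n = int(rng.integers(n_min, n_max + 1))
    while True:
        theta = np.sort(rng.uniform(0, 2 * math.pi, size=n))
        gaps = np.diff(np.concatenate([theta, [theta[0] + 2 * math.pi]]))
        # origin strictly inside (max gap < pi) and no degenerate gaps
        if gaps.min() > 1e-2 and gaps.max() < 2.6:
            break
    r = rng.uniform(0.3, 1.5, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def honeycomb_sheet():
    """A perfect unjittered tessellation: interior cells are regular hexagons."""
    cfg = em.GeneratorConfig(
        window=(150.0, 150.0), target_cell_area=100.0, jitter_sigma=0.0, seed=0
    )
    return em.generate_sheet(cfg)


@pytest.fixture(scope="session")
def jittered_sheet():
    cfg = em.GeneratorConfig(
        window=(200.0, 200.0), target_cell_area=100.0, jitter_sigma=0.3, seed=11,
        raster_px_per_um=2.0,
    )
    return em.generate_sheet(cfg)
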