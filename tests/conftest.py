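import numpy as np
import pytest

from isletmito.synthetic import MovieConfig, MicrodomainSpec, simulate_movie, simulate_ratio_movie


@pytest.fixture(scope="session")
def small_movie():
    """Two-cell noisy movie (one alpha, one not) with ground truth."""
    cfg = MovieConfig(seed=11, n_cells=2, n_frames=10, alpha_fraction=0.5)
    return simulate_movie(cfg)


@pytest.fixture(scope="session")
def clean_alpha_movie():
    """Noise-free all-alpha movie: exact segmentation/classification truth."""
    cfg = MovieConfig(seed=12, n_cells=2, n_frames=8, alpha_fraction=1.0,
                      poisson=False, gaussian_sigma=0.0)
    return simulate_movie(cfg)


@pytest.fixture(scope="session")
def clean_ratio_movie():
    """Noise-free ratio movie with 3 planted microdomains vanishing mid-way."""
    cfg = MovieConfig(seed=13, n_cells=2, n_frames=6, poisson=False,
                      gaussian_sigma=0.0)
    spec = MicrodomainSpec(count=3, radius_um=1.0, ratio_high=2.0,
                           ratio_low=1.0, vanish_at_frame=3)
    return simulate_ratio_movie(cfg, spec)


def star_polygon(rng: np.random.Generator, n_vertices: int = 12,
                 radius: float = 10.0):
    """Random simple (star-shaped) polygon around the origin."""
    from shapely.geometry import Polygon
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(0.3, 1.0, n_vertices) * radius
    return Polygon(np.column_stack([radii * np.cos(angles),
                                    radii * np.sin(angles)]))
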