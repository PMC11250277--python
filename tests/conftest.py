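import numpy as np
import pytest

from msidyn.synth import ImageSpec, gen_cell_image


@pytest.fixture(scope="session")
def benchmark_image():
    """The standard segmentation benchmark: 20 disjoint cells plus 5 touching
    pairs (30 cells) at the generator's default noise and background ramp."""
    spec = ImageSpec(n_cells=30, overlap_pairs=5, seed=123)
    channels, truth = gen_cell_image(spec)
    return spec, channels, truth


@pytest.fixture(scope="session")
def clean_image():
    """A noise-free, ramp-free tile whose foreground is exactly the union of
    the truth ellipses."""
    spec = ImageSpec(n_cells=12, overlap_pairs=0, noise_sd=0.0,
                     gradient_amplitude=0.0, seed=7)
    channels, truth = gen_cell_image(spec)
    return spec, channels, truth


def match_centers(truth, cells, max_dist_px=5.0):
    """Match true ellipse centers to detected cell centers (nearest neighbor).

    Returns (true_detected_rate, rmse_of_matched_centers).
    """
    from scipy.spatial import cKDTree

    true_rc = np.array([[e[1], e[0]] for e in truth.ellipses])
    det_rc = np.array([c.center_rc for c in cells])
    if len(det_rc) == 0:
        return 0.0, np.inf
    d, _ = cKDTree(det_rc).query(true_rc, k=1)
    matched = d <= max_dist_px
    if not matched.any():
        return 0.0, np.inf
    return float(matched.mean()), float(np.sqrt((d[matched] ** 2).mean()))
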