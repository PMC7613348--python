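import numpy as np
import pytest

from sifemu import RadianceCube, SceneConfig, SIFCube, make_band_grid, simulate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return make_band_grid(750.0, 770.0, 5)


@pytest.fixture
def tiny_cube(small_grid):
    # pixel (r, c) stores r*1000 + c in every band
    rows, cols = 4, 3
    vals = np.zeros((rows, cols, len(small_grid)), dtype=np.float32)
    for r in range(rows):
        for c in range(cols):
            vals[r, c, :] = r * 1000 + c
    return RadianceCube(vals, small_grid)


@pytest.fixture(scope="session")
def noisy_scene():
    """One moderately sized noisy scene shared across tests."""
    config = SceneConfig(rows=60, cols=60, n_classes=6, seed=99)
    cube, truth = simulate_scene(config)
    return config, cube, truth


@pytest.fixture
def sif_pair(small_grid):
    def _make(ref_vals, est_vals):
        ref = np.asarray(ref_vals, dtype=np.float32)
        est = np.asarray(est_vals, dtype=np.float32)
        return (SIFCube(ref, small_grid), SIFCube(est, small_grid))
    return _make
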