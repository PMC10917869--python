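import numpy as np
import pytest

import vbgradient as vb


def make_series_with_correlation(corr: float, k: int = 20, seed: int = 0):
    """Two zero-mean length-k series whose sample Pearson correlation is exactly
    ``corr`` (up to float round-off), built from a seeded orthonormal pair."""
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((k, 2))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    e1, e2 = q[:, 0], q[:, 1]
    s1 = e1
    s2 = corr * e1 + np.sqrt(max(1.0 - corr**2, 0.0)) * e2
    return vb.TimeSeriesMatrix(np.vstack([s1, s2]))


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated volume + plane mesh shared by searchlight tests."""
    spec = vb.SimulationSpec(grid_shape=(16, 16, 16), k=40,
                             activations=(vb.Activation((8, 8, 8), 3.0),),
                             seed=5)
    vol = vb.simulate_fmri(spec)
    mesh = vb.flat_grid_mesh(spec)
    return spec, vol, mesh
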