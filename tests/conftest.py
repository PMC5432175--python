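import numpy as np
import pandas as pd
import pytest

import crypticpocket as cp
from crypticpocket.pca import ProjectionSet


@pytest.fixture(scope="session")
def scaffold():
    atoms, coords = cp.base_scaffold(50)
    return atoms, coords


@pytest.fixture(scope="session")
def two_state():
    """Well-separated two-state ensemble with ground-truth labels."""
    spec = cp.TwoStateSpec(n_frames=2000, populations=(0.7, 0.3),
                           noise_sd=0.3, seed=7)
    ensemble, labels = cp.make_two_state_ensemble(spec)
    return spec, ensemble, labels


@pytest.fixture(scope="session")
def loop_selection(two_state):
    _, ensemble, _ = two_state
    return cp.select_loops(ensemble, [(8, 14), (20, 30), (40, 48)],
                           heavy_only=True)


@pytest.fixture(scope="session")
def fitted_two_state(two_state, loop_selection):
    _, ensemble, _ = two_state
    ref = cp.iterative_mean_reference(ensemble, loop_selection)
    fitted, _ = cp.superpose(ensemble, loop_selection, ref.coordinates)
    return fitted


def projection_set(points):
    points = np.asarray(points, dtype=float)
    n = len(points)
    prov = pd.DataFrame({"replica": np.zeros(n, dtype=int),
                         "time_ns": np.arange(n, dtype=float),
                         "source": [""] * n})
    return ProjectionSet(points, prov)


@pytest.fixture
def make_projections():
    return projection_set


def gaussian_mixture_projections(seed, n, weights, centers, sds):
    rng = np.random.default_rng(seed)
    weights = np.asarray(weights, dtype=float)
    labels = rng.choice(len(weights), size=n, p=weights / weights.sum())
    pts = np.empty((n, 2))
    for i, (c, s) in enumerate(zip(centers, sds)):
        mask = labels == i
        pts[mask] = rng.normal(c, s, size=(mask.sum(), 2))
    return projection_set(pts), labels
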