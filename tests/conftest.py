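import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

from speckleflow.synthetic import (
    DISTURBED_PRESET,
    LAMINAR_PRESET,
    generate_speckle_video,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_unit_columns(rng, n, r):
    M = rng.standard_normal((n, r))
    return M / np.linalg.norm(M, axis=0)


def rank_r_tensor(rng, shape, weights):
    """Exactly low-rank tensor with known unit-norm factors and weights."""
    weights = np.asarray(weights, dtype=float)
    r = len(weights)
    A = random_unit_columns(rng, shape[0], r)
    B = random_unit_columns(rng, shape[1], r)
    C = random_unit_columns(rng, shape[2], r)
    X = np.einsum("r,ir,jr,kr->ijk", weights, A, B, C)
    return X, (A, B, C)


@pytest.fixture
def laminar_loop():
    return generate_speckle_video(
        LAMINAR_PRESET, shape=(16, 16), n_frames=400, frame_rate=60.0, seed=7
    )


@pytest.fixture
def disturbed_loop():
    return generate_speckle_video(
        DISTURBED_PRESET, shape=(16, 16), n_frames=400, frame_rate=60.0, seed=7
    )
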