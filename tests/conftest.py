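import math

import numpy as np
import pandas as pd
import pytest

from commitval.commitment import fit
from commitval.synthetic import (
    SimConfig,
    make_fixture,
    simulate_match,
    toy_commitment_model,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_observation_frame(seed=5, n1=60, n0=140):
    """Deterministic small training frame with both classes populated."""
    r = np.random.default_rng(seed)
    committed = pd.DataFrame(
        {
            "velocity": r.uniform(0, 5, n1),
            "time_to_point": r.uniform(1, 3, n1),
            "rel_x": r.normal(0, 2, n1),
            "rel_y": r.normal(1, 2, n1),
            "committed": 1,
        }
    )
    not_committed = pd.DataFrame(
        {
            "velocity": r.uniform(0, 8, n0),
            "time_to_point": r.uniform(1, 4, n0),
            "rel_x": r.normal(0, 12, n0),
            "rel_y": r.normal(0, 12, n0),
            "committed": 0,
        }
    )
    return pd.concat([committed, not_committed]).reset_index(drop=True)


@pytest.fixture(scope="session")
def small_observations():
    return small_observation_frame()


@pytest.fixture(scope="session")
def small_model(small_observations):
    return fit(small_observations)


@pytest.fixture(scope="session")
def toy_model():
    return toy_commitment_model()


@pytest.fixture(scope="session")
def planted_fixture():
    return make_fixture("planted_optimum")


@pytest.fixture(scope="session")
def small_sim():
    """A modest full match used by several pipeline tests."""
    return simulate_match(SimConfig(seed=7, n_plays=60, pass_fraction=0.15))


# ---------------------------------------------------------------------------
# Independent oracle: naive double-loop Gaussian kernel posterior
# ---------------------------------------------------------------------------

def naive_gaussian_density(train: np.ndarray, query: np.ndarray, bandwidth: float) -> float:
    """Mean of product Gaussian kernels, normalized; O(n*d) per query."""
    n, d = train.shape
    total = 0.0
    for i in range(n):
        sq = 0.0
        for j in range(d):
            diff = query[j] - train[i, j]
            sq += diff * diff
        total += math.exp(-sq / (2.0 * bandwidth * bandwidth))
    norm = (2.0 * math.pi * bandwidth * bandwidth) ** (d / 2.0)
    return total / (n * norm)


def naive_commit_probability(observations: pd.DataFrame, bandwidth: float, query) -> float:
    """From-scratch two-class posterior for a single 4-D query point."""
    feats = ["velocity", "time_to_point", "rel_x", "rel_y"]
    X = observations[feats].to_numpy(dtype=float)
    c = observations["committed"].to_numpy()
    X1, X0 = X[c == 1], X[c == 0]
    w = len(X1) / (len(X1) + len(X0))
    q = np.asarray(query, dtype=float)
    f1 = naive_gaussian_density(X1, q, bandwidth)
    f0 = naive_gaussian_density(X0, q, bandwidth)
    denom = w * f1 + (1.0 - w) * f0
    if denom == 0.0:
        return 0.0
    return w * f1 / denom
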