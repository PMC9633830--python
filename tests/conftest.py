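import numpy as np
import pytest

from metalscreen import SimConfig, generate_cohort, knn_weights


@pytest.fixture(scope="session")
def six_point_fixture():
    """Small worked fixture: 6 sites with fixed values, used for loop-based
    oracle comparisons of the spatial statistics."""
    coords = np.array(
        [
            [16.56, -5.44],
            [16.58, -5.43],
            [16.60, -5.41],
            [16.61, -5.38],
            [16.63, -5.37],
            [16.57, -5.40],
        ]
    )
    x = np.array([1.0, 2.0, 4.0, 3.5, 5.0, 2.5])
    y = np.array([2.0, 1.5, 3.0, 4.5, 5.5, 1.0])
    return coords, x, y


@pytest.fixture(scope="session")
def small_cohort():
    """One deterministic synthetic cohort, small enough for fast tests."""
    return generate_cohort(SimConfig(n_children=80, n_clusters=3, seed=11))


@pytest.fixture(scope="session")
def default_cohort():
    """One deterministic cohort at the default survey size."""
    return generate_cohort(SimConfig(seed=7))


def brute_force_lee(x, y, W):
    """Independent loop-based evaluation of global and local Lee's L from
    the dense weight matrix — the oracle for the vectorized implementation."""
    Wd = W.to_dense()
    n = len(x)
    xbar, ybar = np.mean(x), np.mean(y)
    ssx = np.sqrt(sum((xi - xbar) ** 2 for xi in x))
    ssy = np.sqrt(sum((yi - ybar) ** 2 for yi in y))
    denom_w = 0.0
    num = 0.0
    local = np.zeros(n)
    for i in range(n):
        row_sum = 0.0
        lag_x = 0.0
        lag_y = 0.0
        for j in range(n):
            row_sum += Wd[i, j]
            lag_x += Wd[i, j] * (x[j] - xbar)
            lag_y += Wd[i, j] * (y[j] - ybar)
        denom_w += row_sum**2
        num += lag_x * lag_y
        local[i] = n * lag_x * lag_y / (ssx * ssy)
    return n / denom_w * num / (ssx * ssy), local


@pytest.fixture(scope="session")
def null_weights_100():
    """Fixed 100-site k=4 weights for permutation-calibration studies."""
    rng = np.random.default_rng(2024)
    coords = np.column_stack(
        [rng.uniform(16.55, 16.65, 100), rng.uniform(-5.45, -5.35, 100)]
    )
    return knn_weights(coords, k=4)
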