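import numpy as np
import pytest

from spotmap import ModelData, ObjectiveWeights
from spotmap.pairs import SpatialPairSet


def random_instance(
    rng: np.random.Generator,
    n_pops: int = 5,
    n_spots: int = 12,
    n_genes: int = 8,
    n_pairs: int = 4,
    with_prior: bool = True,
    capacity: float = 4.0,
):
    """A small random model instance with strictly positive data and feasible Y."""
    X_S = rng.uniform(0.2, 3.0, (n_spots, n_genes))
    X_R = rng.uniform(0.2, 3.0, (n_pops, n_genes))
    idx = rng.choice(n_spots * (n_spots - 1) // 2, size=min(n_pairs, n_spots // 2), replace=False)
    all_pairs = [(i, j) for i in range(n_spots) for j in range(i + 1, n_spots)]
    pairs_arr = np.asarray([all_pairs[k] for k in sorted(idx)])
    pairs = SpatialPairSet(pairs_arr, rng.uniform(0.6, 1.0, len(pairs_arr)), 1.0, 0.6)
    r = rng.uniform(1.0, 3.0, n_pops) if with_prior else None
    data = ModelData(X_S=X_S, X_R=X_R, pairs=pairs, r=r)
    weights = ObjectiveWeights(
        lambda_C=rng.uniform(0.2, 1.5),
        lambda_G=rng.uniform(0.2, 1.5),
        lambda_S=rng.uniform(0.2, 1.5),
        lambda_A=rng.uniform(0.2, 1.5) if with_prior else 0.0,
        theta=rng.uniform(0.1, 0.9),
        nbar=capacity,
    )
    Y = rng.uniform(0.1, 1.0, (n_pops, n_spots))
    Y = Y / Y.sum(axis=0) * rng.uniform(1.2, 0.9 * capacity, n_spots)
    return data, weights, Y


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
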