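"""Spatial pair set: adjacent, expression-similar spots and their weights.

The local-smoothing objective operates on a set P of spot pairs that are both
spatially adjacent (within a data-driven distance threshold d_bar) and
transcriptionally similar (cosine similarity, over the FULL spatial gene set,
at least w_bar). Thresholds are chosen so that |P| = O(|I|), keeping the
spatial term linear in the number of spots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .containers import SpatialDataset

__all__ = [
    "SpatialPairSet",
    "adjacency_threshold",
    "similarity_cutoff",
    "build_pairs",
]

DEFAULT_SIMILARITY_FLOOR = 0.6
_NN_POOL = 8          # neighbors pooled per spot, mimicking a 2-D grid's 8 adjacent tiles
_PERCENTILE = 90.0    # linear-interpolation percentile of the pooled 8-NN distances


@dataclass
class SpatialPairSet:
    """Pairs (i, j), i < j, with cosine-similarity weights and the thresholds used."""

    pairs: np.ndarray          # |P| x 2 integer spot indices, i < j
    weights: np.ndarray        # w_ij in [-1, 1] (nonnegative data gives [0, 1])
    d_bar: float
    w_bar: float

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if self.pairs.shape[0] != self.weights.shape[0]:
            raise ValueError("pairs and weights length mismatch")

    def __len__(self) -> int:
        return self.pairs.shape[0]

    def to_edge_list(self) -> np.ndarray:
        """(i, j, w_ij) rows, exportable as a 3-column table."""
        return np.column_stack([self.pairs, self.weights])


def adjacency_threshold(coords: np.ndarray) -> float:
    """Distance threshold: 90th percentile of pooled 8-nearest-neighbor distances.

    For each spot, the Euclidean distances to its 8 nearest other spots are
    collected (8|I| values in total) and the 90th percentile (linear
    interpolation between order statistics) is returned. With fewer than 9
    spots the maximum pairwise distance is returned instead. Duplicate
    coordinates contribute their true zero distances.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        return 0.0
    if n < _NN_POOL + 1:
        diffs = coords[:, None, :] - coords[None, :, :]
        return float(np.sqrt((diffs**2).sum(-1)).max())
    tree = cKDTree(coords)
    dists, _ = tree.query(coords, k=_NN_POOL + 1)  # first column is self (0)
    return float(np.percentile(dists[:, 1:].ravel(), _PERCENTILE))


def _candidate_pairs(spatial: SpatialDataset, d_bar: float) -> tuple[np.ndarray, np.ndarray]:
    """All (i<j) pairs within d_bar and their cosine weights over all spatial genes."""
    coords = spatial.coords
    tree = cKDTree(coords)
    raw = tree.query_pairs(d_bar, output_type="ndarray")
    if raw.size == 0:
        return np.empty((0, 2), dtype=int), np.empty(0)
    raw = np.sort(raw, axis=1)
    order = np.lexsort((raw[:, 1], raw[:, 0]))
    raw = raw[order]

    X = spatial.expr.values
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} spot(s) have all-zero expression; they join no "
            "spatial pair (cosine similarity undefined)",
            stacklevel=2,
        )
        keep = ~(zero[raw[:, 0]] | zero[raw[:, 1]])
        raw = raw[keep]
        if raw.size == 0:
            return np.empty((0, 2), dtype=int), np.empty(0)
    w = np.einsum("ij,ij->i", X[raw[:, 0]], X[raw[:, 1]])
    w = w / (norms[raw[:, 0]] * norms[raw[:, 1]])
    return raw, np.clip(w, -1.0, 1.0)


def similarity_cutoff(
    spatial: SpatialDataset,
    d_bar: float,
    floor: float = DEFAULT_SIMILARITY_FLOOR,
) -> float:
    """Similarity cutoff w_bar = max(floor, value keeping at most |I| pairs).

    Candidate pairs within d_bar are ranked by cosine similarity; when more
    than |I| candidates clear the floor, the cutoff moves up to the |I|-th
    largest similarity. Ties at the cutoff are retained by
    :func:`build_pairs`, so |P| may slightly exceed |I| under ties.
    """
    if not -1.0 <= floor <= 1.0:
        raise ValueError("similarity floor must lie in [-1, 1]")
    _, w = _candidate_pairs(spatial, d_bar)
    n_spots = spatial.n_spots
    above = w[w >= floor]
    if above.size <= n_spots:
        return float(floor)
    return float(np.sort(above)[::-1][n_spots - 1])


def build_pairs(spatial: SpatialDataset, d_bar: float, w_bar: float) -> SpatialPairSet:
    """Assemble P = {(i, j): i < j, dist <= d_bar, w_ij >= w_bar}."""
    if not (np.isfinite(d_bar) and np.isfinite(w_bar)):
        raise ValueError("thresholds must be finite")
    cand, w = _candidate_pairs(spatial, d_bar)
    keep = w >= w_bar
    return SpatialPairSet(cand[keep], w[keep], float(d_bar), float(w_bar))


def auto_pairs(
    spatial: SpatialDataset,
    floor: float = DEFAULT_SIMILARITY_FLOOR,
    d_bar: float | None = None,
    w_bar: float | None = None,
) -> SpatialPairSet:
    """Data-driven pair set: infer d_bar and w_bar unless overridden."""
    if d_bar is None:
        d_bar = adjacency_threshold(spatial.coords)
    if w_bar is None:
        w_bar = similarity_cutoff(spatial, d_bar, floor=floor)
    return build_pairs(spatial, d_bar, w_bar)
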