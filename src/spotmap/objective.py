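"""The multi-objective transfer model: five penalty terms, their sum, and its gradient.

Let Y be the (sub-)populations x spots transfer matrix, X_S the spots x genes
spatial expression over the shared gene set, and X_R the centroids over the
same genes. The model combines

* a per-spot expression match (square-root cosine distance between each
  spot's profile and the profile transferred to it), blended by a sparsity
  parameter theta with a linear term that promotes pure, one-population spots;
* a per-population match between each centroid and the expression mass Y
  assigns to it;
* a per-gene match between each gene's spatial map and its transferred map;
* a local spatial-coherence penalty: Jensen-Shannon divergence between the
  composition columns of adjacent, expression-similar spot pairs;
* an optional match between total transferred abundance per population and an
  expected-abundance prior, again via Jensen-Shannon divergence.

The distance d_cos(a, b) = sqrt(1 - cos(a, b)) is a scale-invariant metric on
rays of the positive orthant. Jensen-Shannon divergences are computed in base
2 directly on the raw (unnormalized) nonnegative vectors, which bounds the
spatial term by n|P|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import rel_entr

from .pairs import SpatialPairSet

__all__ = [
    "ObjectiveWeights",
    "ObjectiveBreakdown",
    "ModelData",
    "cosine_metric",
    "js_divergence",
    "term_spots",
    "term_populations",
    "term_genes",
    "term_spatial",
    "term_abundance",
    "total_objective",
    "gradient",
]

_LN2 = np.log(2.0)
# smoothing floors for differentiation only; reported objective values are unsmoothed
_EPS_COS = 1e-9    # clamp on 1 - cos inside the square root's derivative
_EPS_LOG = 1e-12   # floor on JS log arguments
_EPS_NORM = 1e-300


@dataclass
class ObjectiveWeights:
    """Penalty weights, sparsity level, and the per-spot sparsity scaling n_bar."""

    lambda_C: float = 0.0
    lambda_G: float = 0.0
    lambda_S: float = 0.0
    lambda_A: float = 0.0
    theta: float = 0.0
    nbar: float | np.ndarray = 1.0

    def __post_init__(self) -> None:
        for name in ("lambda_C", "lambda_G", "lambda_S", "lambda_A"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if np.any(np.asarray(self.nbar) < 1):
            raise ValueError("nbar must be >= 1")


@dataclass
class ObjectiveBreakdown:
    """Raw term values plus the lambda-weighted total."""

    term_spots: float
    term_pops: float
    term_genes: float
    term_spatial: float
    term_abund: float
    total: float


@dataclass
class ModelData:
    """Everything the objective needs besides Y.

    ``X_S`` and ``X_R`` are restricted to the shared gene set. ``parent_index``
    maps each row of Y to a population index for the abundance prior (identity
    when no sub-clustering was done); ``r`` is the scaled prior or None.
    """

    X_S: np.ndarray                       # |I| x |G|
    X_R: np.ndarray                       # |C'| x |G|
    pairs: SpatialPairSet | None = None
    r: np.ndarray | None = None           # prior over populations, scaled
    parent_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X_S = np.asarray(self.X_S, dtype=float)
        self.X_R = np.asarray(self.X_R, dtype=float)
        if self.X_S.shape[1] != self.X_R.shape[1]:
            raise ValueError("X_S and X_R must share the gene axis")
        if self.r is not None:
            self.r = np.asarray(self.r, dtype=float)
            if self.parent_index is None:
                self.parent_index = np.arange(self.X_R.shape[0])
            self.parent_index = np.asarray(self.parent_index, dtype=int)

    # cached spot-vs-centroid distance matrix (constant in Y)
    _centroid_dist: np.ndarray | None = None

    def centroid_distances(self) -> np.ndarray:
        """d_cos between every centroid row and every spot row; |C'| x |I|."""
        if self._centroid_dist is None:
            self._centroid_dist = _pairwise_cosdist(self.X_R, self.X_S)
        return self._centroid_dist


# ---------------------------------------------------------------------------
# primitive metrics


def cosine_metric(a: np.ndarray, b: np.ndarray) -> float:
    """sqrt(1 - cos(a, b)): a scale-invariant metric for nonnegative vectors.

    An all-zero vector is at distance 1 from any nonzero vector and 0 from
    another all-zero vector (bounded degenerate-input policy).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 and nb == 0.0:
        return 0.0
    if na == 0.0 or nb == 0.0:
        return 1.0
    # ||a/|a| - b/|b||^2 = 2 - 2 cos: exact at collinearity, stable near it
    diff = a / na - b / nb
    return float(min(1.0, np.linalg.norm(diff) / np.sqrt(2.0)))


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence, base 2, applied to raw nonnegative vectors.

    JS(p, q) = 0.5 KL(p || m) + 0.5 KL(q || m) with m = (p + q)/2 and the
    convention 0 log 0 = 0. For probability vectors the value lies in [0, 1];
    for mass-m vectors with disjoint support it equals m.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have equal length")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("Jensen-Shannon inputs must be nonnegative")
    m = 0.5 * (p + q)
    return float((rel_entr(p, m).sum() + rel_entr(q, m).sum()) / (2.0 * _LN2))


# ---------------------------------------------------------------------------
# vectorized d_cos helpers (paired rows / columns, degenerate policy built in)


def _paired_cosdist(A: np.ndarray, B: np.ndarray, axis: int = 1) -> np.ndarray:
    """d_cos between corresponding rows (axis=1) or columns (axis=0) of A and B."""
    na = np.linalg.norm(A, axis=axis)
    nb = np.linalg.norm(B, axis=axis)
    sh = (-1, 1) if axis == 1 else (1, -1)
    diff = A / np.maximum(na, _EPS_NORM).reshape(sh) - B / np.maximum(
        nb, _EPS_NORM
    ).reshape(sh)
    d = np.minimum(1.0, np.linalg.norm(diff, axis=axis) / np.sqrt(2.0))
    both_zero = (na == 0) & (nb == 0)
    one_zero = (na == 0) ^ (nb == 0)
    d = np.where(both_zero, 0.0, d)
    return np.where(one_zero, 1.0, d)


def _pairwise_cosdist(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """d_cos between every row of A and every row of B; shape (len(A), len(B))."""
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    s = (A @ B.T) / np.maximum(np.outer(na, nb), _EPS_NORM)
    d = np.sqrt(np.clip(1.0 - s, 0.0, None))
    za, zb = na == 0, nb == 0
    both = np.outer(za, zb)
    one = np.outer(za, ~zb) | np.outer(~za, zb)
    d = np.where(both, 0.0, d)
    return np.where(one, 1.0, d)


def _paired_cosdist_grad_b(
    A: np.ndarray, B: np.ndarray, axis: int = 1
) -> np.ndarray:
    """Gradient of d_cos(A_k, B_k) with respect to B, row- or column-paired.

    Uses the smoothed surrogate: 1 - cos is clamped at _EPS_COS inside the
    square root's derivative so the slope stays finite as cos -> 1. Degenerate
    (zero-norm) pairs get zero gradient.
    """
    na = np.linalg.norm(A, axis=axis)
    nb = np.linalg.norm(B, axis=axis)
    denom = np.maximum(na * nb, _EPS_NORM)
    s = (A * B).sum(axis=axis) / denom
    coef = -0.5 / np.sqrt(np.maximum(1.0 - s, _EPS_COS))
    ok = (na > 0) & (nb > 0)
    coef = np.where(ok, coef, 0.0)
    if axis == 1:
        sh = (-1, 1)
    else:
        sh = (1, -1)
    grad = coef.reshape(sh) * (
        A / denom.reshape(sh)
        - (s / np.maximum(nb**2, _EPS_NORM)).reshape(sh) * B
    )
    return grad


def _js_grad_p(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """d JS(p, q) / d p = 0.5 log2(2p / (p + q)), with floored log arguments."""
    num = np.maximum(2.0 * p, _EPS_LOG)
    den = np.maximum(p + q, _EPS_LOG)
    return 0.5 * np.log2(num / den)


# ---------------------------------------------------------------------------
# objective terms


def _transferred(Y: np.ndarray, X_R: np.ndarray) -> np.ndarray:
    """M = Y^T X_R: row i is the profile transferred to spot i; column g is the
    transferred spatial map of gene g."""
    return Y.T @ X_R


def term_spots(
    Y: np.ndarray,
    X_S: np.ndarray,
    X_R: np.ndarray,
    theta: float = 0.0,
    nbar: float | np.ndarray = 1.0,
    centroid_dist: np.ndarray | None = None,
) -> float:
    """Per-spot expression match blended with the sparsity-promoting linear term.

    sum_i [(1-theta) d_cos(x_i, sum_c Y_ci X_R_c) +
           (theta/nbar_i) sum_c Y_ci d_cos(x_i, X_R_c)]
    """
    M = _transferred(Y, X_R)
    val = (1.0 - theta) * _paired_cosdist(X_S, M, axis=1).sum()
    if theta > 0:
        if centroid_dist is None:
            centroid_dist = _pairwise_cosdist(X_R, X_S)
        nbar_arr = np.broadcast_to(np.asarray(nbar, dtype=float), (X_S.shape[0],))
        val += theta * ((Y * centroid_dist).sum(axis=0) / nbar_arr).sum()
    return float(val)


def term_populations(Y: np.ndarray, X_S: np.ndarray, X_R: np.ndarray) -> float:
    """sum_c d_cos(X_R_c, sum_i Y_ci x_i): each centroid vs its transferred mass."""
    T = Y @ X_S
    return float(_paired_cosdist(X_R, T, axis=1).sum())


def term_genes(Y: np.ndarray, X_S: np.ndarray, X_R: np.ndarray) -> float:
    """sum_g d_cos(X_S_:,g, (Y^T X_R)_:,g): spatial map of each shared gene."""
    M = _transferred(Y, X_R)
    return float(_paired_cosdist(X_S, M, axis=0).sum())


def term_spatial(Y: np.ndarray, pairs: SpatialPairSet) -> float:
    """sum over pairs of w_ij * JS(Y_:,i, Y_:,j), base 2, raw columns."""
    if pairs is None or len(pairs) == 0:
        return 0.0
    p = Y[:, pairs.pairs[:, 0]]
    q = Y[:, pairs.pairs[:, 1]]
    m = 0.5 * (p + q)
    js = (rel_entr(p, m).sum(axis=0) + rel_entr(q, m).sum(axis=0)) / (2.0 * _LN2)
    return float((pairs.weights * js).sum())


def term_abundance(
    Y: np.ndarray, r: np.ndarray, parent_index: np.ndarray | None = None
) -> float:
    """JS between the per-population transferred mass rho and the prior r.

    ``parent_index`` maps Y rows (sub-clusters) to positions in r; identity
    when absent.
    """
    r = np.asarray(r, dtype=float)
    if np.all(r == 0):
        raise ValueError("abundance prior must not be all zero")
    row_mass = Y.sum(axis=1)
    if parent_index is None:
        rho = row_mass
    else:
        rho = np.zeros(len(r))
        np.add.at(rho, np.asarray(parent_index, dtype=int), row_mass)
    return js_divergence(rho, r)


def total_objective(
    Y: np.ndarray, data: ModelData, weights: ObjectiveWeights
) -> ObjectiveBreakdown:
    """Weighted sum of the five terms; the spot term carries unit weight."""
    cdist = data.centroid_distances() if weights.theta > 0 else None
    t_spots = term_spots(
        Y, data.X_S, data.X_R, weights.theta, weights.nbar, centroid_dist=cdist
    )
    t_pops = term_populations(Y, data.X_S, data.X_R) if weights.lambda_C > 0 else 0.0
    t_genes = term_genes(Y, data.X_S, data.X_R) if weights.lambda_G > 0 else 0.0
    t_spatial = (
        term_spatial(Y, data.pairs)
        if weights.lambda_S > 0 and data.pairs is not None
        else 0.0
    )
    t_abund = (
        term_abundance(Y, data.r, data.parent_index)
        if weights.lambda_A > 0 and data.r is not None
        else 0.0
    )
    total = (
        t_spots
        + weights.lambda_C * t_pops
        + weights.lambda_G * t_genes
        + weights.lambda_S * t_spatial
        + weights.lambda_A * t_abund
    )
    return ObjectiveBreakdown(t_spots, t_pops, t_genes, t_spatial, t_abund, float(total))


def gradient(
    Y: np.ndarray, data: ModelData, weights: ObjectiveWeights
) -> np.ndarray:
    """Gradient of the total objective with respect to Y (smoothed surrogates).

    The spot and gene terms share the transferred matrix M = Y^T X_R: the spot
    term differentiates d_cos along M's rows, the gene term along its columns;
    both chain back through X_R. The population term chains through X_S. The
    Jensen-Shannon terms use the closed form 0.5 log2(2p/(p+q)).
    """
    X_S, X_R = data.X_S, data.X_R
    n_spots = X_S.shape[0]
    M = _transferred(Y, X_R)
    grad = np.zeros_like(Y)

    theta = weights.theta
    if theta < 1.0:
        D = _paired_cosdist_grad_b(X_S, M, axis=1)   # |I| x |G|
        grad += (1.0 - theta) * (X_R @ D.T)
    if theta > 0.0:
        nbar_arr = np.broadcast_to(np.asarray(weights.nbar, dtype=float), (n_spots,))
        grad += theta * data.centroid_distances() / nbar_arr

    if weights.lambda_C > 0:
        T = Y @ X_S
        F = _paired_cosdist_grad_b(X_R, T, axis=1)   # |C'| x |G|
        grad += weights.lambda_C * (F @ X_S.T)

    if weights.lambda_G > 0:
        E = _paired_cosdist_grad_b(X_S, M, axis=0)   # |I| x |G|, column-paired
        grad += weights.lambda_G * (X_R @ E.T)

    if weights.lambda_S > 0 and data.pairs is not None and len(data.pairs) > 0:
        ii = data.pairs.pairs[:, 0]
        jj = data.pairs.pairs[:, 1]
        w = data.pairs.weights
        p = Y[:, ii]
        q = Y[:, jj]
        gp = w * _js_grad_p(p, q)
        gq = w * _js_grad_p(q, p)
        contrib = np.zeros_like(Y)
        np.add.at(contrib.T, ii, (weights.lambda_S * gp).T)
        np.add.at(contrib.T, jj, (weights.lambda_S * gq).T)
        grad += contrib

    if weights.lambda_A > 0 and data.r is not None:
        row_mass = Y.sum(axis=1)
        pi = data.parent_index
        rho = np.zeros(len(data.r))
        np.add.at(rho, pi, row_mass)
        g_rho = _js_grad_p(rho, data.r)
        grad += weights.lambda_A * g_rho[pi][:, None]

    return grad
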