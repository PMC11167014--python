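"""Evaluation metrics for predicted spot compositions.

For single-cell-resolution spots the ground truth is one-hot (the spot's cell
type); prediction quality is measured by classification accuracy, the Brier
score over membership probabilities, and a spatially smoothed Jensen-Shannon
divergence that credits predictions matching the local cell-type neighborhood
rather than only the exact label. For multicell spots the truth is a relative
composition per spot and per-spot JS divergences apply directly.
"""

from __future__ import annotations

import numpy as np

from .objective import js_divergence

__all__ = [
    "GroundTruth",
    "accuracy",
    "brier",
    "smoothed_truth",
    "spatial_js",
    "per_spot_js",
]


class GroundTruth:
    """Column-stochastic truth matrix (populations x spots) with coordinates.

    High-resolution truth has one-hot columns; low-resolution truth has
    relative-abundance columns. Coordinates are needed only for smoothing.
    """

    def __init__(
        self,
        P: np.ndarray,
        row_ids: list[str],
        coords: np.ndarray | None = None,
    ) -> None:
        self.P = np.asarray(P, dtype=float)
        if np.any(self.P < 0):
            raise ValueError("ground-truth entries must be nonnegative")
        if not np.allclose(self.P.sum(axis=0), 1.0, atol=1e-8):
            raise ValueError("ground-truth columns must sum to 1")
        self.row_ids = list(row_ids)
        self.coords = None if coords is None else np.asarray(coords, dtype=float)

    @classmethod
    def from_labels(
        cls, labels: np.ndarray, row_ids: list[str], coords: np.ndarray | None = None
    ) -> "GroundTruth":
        labels = np.asarray(labels)
        pos = {c: k for k, c in enumerate(row_ids)}
        P = np.zeros((len(row_ids), len(labels)))
        for i, lab in enumerate(labels):
            P[pos[str(lab)], i] = 1.0
        return cls(P, row_ids, coords)


def accuracy(pred_labels: np.ndarray, true_labels: np.ndarray) -> float:
    """Proportion of spots whose predicted category matches the truth."""
    pred_labels = np.asarray(pred_labels)
    true_labels = np.asarray(true_labels)
    if pred_labels.shape != true_labels.shape:
        raise ValueError("label vectors must have equal length")
    return float(np.mean(pred_labels == true_labels))


def brier(Y_prob: np.ndarray, P: np.ndarray) -> float:
    """Mean squared error between predicted probabilities and the truth matrix.

    |I|^-1 sum_i sum_c (Y_ci - P_ci)^2; lower means better-calibrated.
    """
    Y_prob = np.asarray(Y_prob, dtype=float)
    P = np.asarray(P, dtype=float)
    if Y_prob.shape != P.shape:
        raise ValueError("prediction and truth shapes differ")
    return float(((Y_prob - P) ** 2).sum() / Y_prob.shape[1])


def smoothed_truth(P: np.ndarray, coords: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-kernel smoothing of the truth columns over space.

    P_tilde_ci = (sum_j K_ij)^-1 sum_j K_ij P_cj with
    K_ij = exp(-||x_i - x_j||^2 / (2 sigma^2)); the self term K_ii = 1 is
    included. Columns remain probability vectors. A sensible default for
    ``sigma`` is half the adjacency distance threshold.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    coords = np.asarray(coords, dtype=float)
    P = np.asarray(P, dtype=float)
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    K = np.exp(-d2 / (2.0 * sigma**2))
    return (P @ K) / K.sum(axis=0)


def spatial_js(Y_prob: np.ndarray, P_tilde: np.ndarray) -> float:
    """Mean base-2 JS divergence between predicted and smoothed-truth columns."""
    return float(np.mean(per_spot_js(Y_prob, P_tilde)))


def per_spot_js(Y_rel: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Base-2 JS divergence per spot between two column-probability matrices."""
    Y_rel = np.asarray(Y_rel, dtype=float)
    P = np.asarray(P, dtype=float)
    if Y_rel.shape != P.shape:
        raise ValueError("prediction and truth shapes differ")
    return np.asarray(
        [js_divergence(Y_rel[:, i], P[:, i]) for i in range(Y_rel.shape[1])]
    )
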