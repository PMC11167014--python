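"""End-to-end annotation transfer: reference prep, pair graph, autoconfig, solve.

``fit_transfer`` is the main user entry point. It builds (sub-)population
centroids, aligns genes, constructs the spatial pair set, infers any
unspecified hyperparameters, runs the Frank-Wolfe solver at sub-cluster
resolution, and collapses the result back to population level. Helper
post-processing (spot sizes, relative abundances, hard labels, continuous
feature transfer) operates on the returned transfer map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig, infer_capacity, infer_weights, infer_theta
from .containers import (
    AbundancePrior,
    ReferenceData,
    SpatialDataset,
    TransferMap,
    ValidationError,
)
from .io import align_genes
from .objective import ModelData, ObjectiveWeights
from .pairs import auto_pairs
from .reference import collapse, compute_centroids, subcluster
from .solver import SolverSettings, SolveTrace, fit

__all__ = [
    "TransferResult",
    "fit_transfer",
    "spot_sizes",
    "relative_abundance",
    "hard_labels",
    "transfer_features",
]


@dataclass
class TransferResult:
    """Population-level transfer map plus run diagnostics."""

    transfer_map: TransferMap          # populations x spots
    sub_map: TransferMap               # (sub-)clusters x spots, pre-collapse
    trace: SolveTrace
    effective: dict                    # all effective hyperparameters

    @property
    def spot_sizes(self) -> np.ndarray:
        return self.transfer_map.spot_sizes


def _total_count_scale(values: np.ndarray) -> np.ndarray:
    totals = values.sum(axis=1, keepdims=True)
    mean_total = totals[totals > 0].mean() if np.any(totals > 0) else 1.0
    scale = np.where(totals > 0, mean_total / np.maximum(totals, 1e-300), 1.0)
    return values * scale


def fit_transfer(
    ref: ReferenceData,
    spatial: SpatialDataset,
    config: ModelConfig | None = None,
    prior: AbundancePrior | None = None,
) -> TransferResult:
    """Transfer reference annotations onto spatial spots.

    Stages: (1) kappa sub-clustering of each reference population on all
    reference genes; (2) gene alignment by exact identifier; (3) spatial pair
    construction on the full spatial gene set; (4) hyperparameter inference
    for anything not pinned in ``config``; (5) Frank-Wolfe solve; (6) collapse
    of sub-cluster rows to populations. Deterministic given ``config.seed``.
    """
    config = config or ModelConfig()

    ref_expr = ref.expr
    sp = spatial
    if config.normalize_totals:
        ref_expr = type(ref_expr)(
            _total_count_scale(ref_expr.values), ref_expr.row_ids, ref_expr.gene_ids
        )
        sp = SpatialDataset(
            type(sp.expr)(
                _total_count_scale(sp.expr.values), sp.expr.row_ids, sp.expr.gene_ids
            ),
            sp.coords,
        )
        ref = ReferenceData(ref_expr, ref.labels)

    # 1. reference profiles on all reference genes
    try:
        if config.kappa == 1:
            profiles = compute_centroids(ref)
        else:
            profiles = subcluster(
                ref,
                kappa=config.kappa,
                min_fraction=config.min_fraction,
                seed=config.seed,
                log_transform=config.ref_log_transform,
            )
    except ValidationError as err:
        raise ValidationError(f"reference preparation: {err}") from err

    # 2. align genes; shared set in spatial order
    shared_idx, _ = align_genes(ref.expr, sp)
    shared_genes = [sp.expr.gene_ids[i] for i in shared_idx]
    ref_gene_pos = {g: i for i, g in enumerate(profiles.gene_ids)}
    prof_idx = np.asarray([ref_gene_pos[g] for g in shared_genes], dtype=int)
    X_R = profiles.X_R[:, prof_idx]
    X_S = sp.expr.values[:, shared_idx]

    # 3. spatial pair set over the full spatial gene panel
    pair_set = auto_pairs(
        sp, floor=config.similarity_floor, d_bar=config.d_bar, w_bar=config.w_bar
    )

    # 4. hyperparameters
    mode = config.resolution.mode
    n = infer_capacity(config.resolution, sp.n_spots)
    inferred = infer_weights(
        sp.n_spots,
        X_R.shape[0],
        len(shared_genes),
        len(pair_set),
        n,
        mode,
        has_prior=prior is not None,
    )
    weights = ObjectiveWeights(
        lambda_C=config.lambda_C if config.lambda_C is not None else inferred.lambda_C,
        lambda_G=config.lambda_G if config.lambda_G is not None else inferred.lambda_G,
        lambda_S=config.lambda_S if config.lambda_S is not None else inferred.lambda_S,
        lambda_A=config.lambda_A if config.lambda_A is not None else inferred.lambda_A,
        theta=config.theta if config.theta is not None else infer_theta(mode),
        nbar=n,
    )

    r_scaled = None
    parent_index = None
    pops = profiles.populations
    if prior is not None and weights.lambda_A > 0:
        missing = [c for c in pops if c not in prior.categories]
        if missing:
            raise ValidationError(f"prior missing categories: {missing}")
        order = [prior.categories.index(c) for c in pops]
        r_scaled = prior.scaled(n * sp.n_spots).r[order]
        pop_pos = {c: k for k, c in enumerate(pops)}
        parent_index = np.asarray(
            [pop_pos[profiles.parent[rid]] for rid in profiles.row_ids], dtype=int
        )

    data = ModelData(X_S=X_S, X_R=X_R, pairs=pair_set, r=r_scaled, parent_index=parent_index)

    # 5. solve
    settings = SolverSettings(
        max_iters=config.max_iters,
        tol=config.tol,
        step_rule=config.step_rule,
        seed=config.seed,
    )
    Y, trace = fit(data, weights, n, settings)

    sub_map = TransferMap(Y, list(profiles.row_ids), list(sp.spot_ids), n)
    pop_map = collapse(sub_map, profiles.parent)

    effective = {
        "mode": mode,
        "capacity": n,
        "lambda_C": weights.lambda_C,
        "lambda_G": weights.lambda_G,
        "lambda_S": weights.lambda_S,
        "lambda_A": weights.lambda_A,
        "theta": weights.theta,
        "kappa": config.kappa,
        "min_fraction": config.min_fraction,
        "d_bar": pair_set.d_bar,
        "w_bar": pair_set.w_bar,
        "num_pairs": len(pair_set),
        "num_shared_genes": len(shared_genes),
        "num_rows": X_R.shape[0],
        "num_spots": sp.n_spots,
        "seed": config.seed,
        "max_iters": config.max_iters,
        "tol": config.tol,
        "step_rule": config.step_rule,
        "iterations": len(trace.step_sizes),
        "final_objective": trace.objective[-1],
    }
    return TransferResult(pop_map, sub_map, trace, effective)


def spot_sizes(Y: TransferMap) -> np.ndarray:
    """Estimated cells per spot: the column sums of the transfer map."""
    return Y.spot_sizes


def relative_abundance(Y: TransferMap) -> np.ndarray:
    """Column-normalized transfer map: per-spot composition probabilities."""
    sums = Y.Y.sum(axis=0)
    if np.any(sums <= 0):
        raise ValueError("relative abundance undefined for zero-mass spots")
    return Y.Y / sums


def hard_labels(Y: TransferMap) -> np.ndarray:
    """Most abundant population per spot (ties: first row)."""
    idx = np.argmax(Y.Y, axis=0)
    return np.asarray([Y.row_ids[i] for i in idx])


def transfer_features(
    Y: TransferMap,
    feature_table: pd.DataFrame,
    normalize: bool | None = None,
) -> pd.DataFrame:
    """Estimate per-spot values of features known only per (sub-)population.

    ``feature_table`` is (sub-)populations x features, indexed to match Y's
    rows; the prediction is the Y-weighted mix of the population values. With
    ``normalize`` (default: True when all spot capacities are 1, i.e. the
    mixing weights become membership probabilities; False otherwise) columns
    of Y are normalized to sum to 1 before mixing.
    """
    missing = [r for r in Y.row_ids if r not in feature_table.index]
    if missing:
        raise ValidationError(f"feature table missing rows: {missing[:5]}")
    F = feature_table.loc[Y.row_ids].to_numpy(dtype=float)
    if normalize is None:
        normalize = bool(np.all(Y.capacity == 1.0))
    W = Y.Y
    if normalize:
        sums = W.sum(axis=0)
        W = W / np.where(sums > 0, sums, 1.0)
    pred = W.T @ F
    return pd.DataFrame(pred, index=Y.col_ids, columns=feature_table.columns)
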