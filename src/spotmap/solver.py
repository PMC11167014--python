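"""Frank-Wolfe (conditional gradient) solver for the transfer model.

The feasible set — nonnegative Y with per-spot column sums in [1, n_i] — is a
product of simple polytopes, one per spot, so the linearized problem at each
iteration decomposes into independent per-spot subproblems with a closed-form
vertex solution: put all mass on the category with the smallest gradient
coefficient, at level n_i if that coefficient is negative and 1 otherwise.
Iterates stay feasible because each step is a convex combination of feasible
points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .objective import ModelData, ObjectiveWeights, total_objective, gradient

__all__ = ["SolverSettings", "SolveTrace", "solve_subproblem_column", "fw_step", "fit"]

_ARMIJO_C1 = 1e-4
_GAMMA_MIN = 1e-10
_GAP_TOL = 1e-12


@dataclass
class SolverSettings:
    """Loop control for the Frank-Wolfe iteration.

    ``step_rule`` is "backtracking" (Armijo line search on the segment towards
    the atom; monotone descent) or "diminishing" (gamma_t = 2/(t+2)). The
    solver itself is deterministic; ``seed`` is carried for API symmetry with
    the stochastic stages of the pipeline.
    """

    max_iters: int = 200
    tol: float = 1e-5
    step_rule: str = "backtracking"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be nonnegative")
        if self.step_rule not in ("backtracking", "diminishing"):
            raise ValueError(f"unknown step rule {self.step_rule!r}")


@dataclass
class SolveTrace:
    """Objective value and step size per iteration (index 0 is the start point)."""

    objective: list[float] = field(default_factory=list)
    step_sizes: list[float] = field(default_factory=list)

    def to_rows(self) -> list[tuple[int, float, float]]:
        steps = [float("nan")] + self.step_sizes
        return [(t, f, steps[t]) for t, f in enumerate(self.objective)]


def solve_subproblem_column(delta_col: np.ndarray, n_i: float) -> np.ndarray:
    """Closed-form minimizer of <y, delta> over {y >= 0, 1 <= sum(y) <= n_i}.

    All mass goes to the smallest coefficient c_hat (ties: lowest index), at
    level n_i when that coefficient is negative and 1 otherwise.
    """
    delta_col = np.asarray(delta_col, dtype=float)
    if not np.all(np.isfinite(delta_col)):
        raise ValueError("subproblem coefficients must be finite")
    c_hat = int(np.argmin(delta_col))
    atom = np.zeros_like(delta_col)
    atom[c_hat] = n_i if delta_col[c_hat] < 0 else 1.0
    return atom


def _atom_matrix(grad: np.ndarray, capacity: np.ndarray) -> np.ndarray:
    """Vectorized per-column subproblem solutions."""
    c_hat = np.argmin(grad, axis=0)
    cols = np.arange(grad.shape[1])
    level = np.where(grad[c_hat, cols] < 0, capacity, 1.0)
    atoms = np.zeros_like(grad)
    atoms[c_hat, cols] = level
    return atoms


def fw_step(Y_t: np.ndarray, atom: np.ndarray, gamma: float) -> np.ndarray:
    """Convex combination (1 - gamma) Y_t + gamma * atom; preserves feasibility."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    return (1.0 - gamma) * Y_t + gamma * atom


def fit(
    data: ModelData,
    weights: ObjectiveWeights,
    capacity: float | np.ndarray,
    settings: SolverSettings | None = None,
    Y0: np.ndarray | None = None,
) -> tuple[np.ndarray, SolveTrace]:
    """Run Frank-Wolfe to (approximate) stationarity; returns (Y, trace).

    Starts from uniform columns (sum 1). Stops when the relative objective
    change drops below ``tol``, the Frank-Wolfe gap vanishes (first-order
    optimality — immediate for purely linear objectives), or ``max_iters``.
    """
    settings = settings or SolverSettings()
    n_rows = data.X_R.shape[0]
    n_cols = data.X_S.shape[0]
    cap = np.broadcast_to(np.asarray(capacity, dtype=float), (n_cols,)).copy()
    if np.any(cap < 1):
        raise ValueError("spot capacity must be >= 1")

    Y = np.full((n_rows, n_cols), 1.0 / n_rows) if Y0 is None else Y0.copy()
    f = total_objective(Y, data, weights).total
    if not np.isfinite(f):
        bk = total_objective(Y, data, weights)
        for name in ("term_spots", "term_pops", "term_genes", "term_spatial", "term_abund"):
            if not np.isfinite(getattr(bk, name)):
                raise ValueError(f"objective term {name} is non-finite at the start point")
        raise ValueError("objective is non-finite at the start point")

    trace = SolveTrace(objective=[f])
    for t in range(settings.max_iters):
        g = gradient(Y, data, weights)
        atoms = _atom_matrix(g, cap)
        direction = atoms - Y
        gap = float((g * direction).sum())  # <= 0 by construction
        if gap >= -_GAP_TOL:
            break

        if settings.step_rule == "diminishing":
            gamma = 2.0 / (t + 2.0)
            Y_new = fw_step(Y, atoms, gamma)
            f_new = total_objective(Y_new, data, weights).total
        else:
            gamma = 1.0
            f_new = None
            while gamma > _GAMMA_MIN:
                cand = fw_step(Y, atoms, gamma)
                f_cand = total_objective(cand, data, weights).total
                if f_cand <= f + _ARMIJO_C1 * gamma * gap:
                    Y_new, f_new = cand, f_cand
                    break
                gamma *= 0.5
            if f_new is None:
                break  # no descent step found: numerically stationary

        rel_change = abs(f - f_new) / max(abs(f), 1e-12)
        Y, f = Y_new, f_new
        trace.objective.append(f)
        trace.step_sizes.append(gamma)
        if rel_change < settings.tol:
            break
    return Y, trace
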