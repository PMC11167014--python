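"""Core data containers: expression matrices, spatial datasets, references, transfer maps.

All containers validate on construction. Orientation conventions:

* ``ExpressionMatrix`` rows are observations (cells or spots), columns are genes.
* ``TransferMap.Y`` rows are (sub-)populations, columns are spots — the
  orientation the optimizer works in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "SpatialDataset",
    "ReferenceData",
    "TransferMap",
    "AbundancePrior",
]


class ValidationError(ValueError):
    """Raised when a container invariant is violated."""


def _check_unique(ids, what: str) -> list[str]:
    ids = [str(x).strip() for x in ids]
    if len(set(ids)) != len(ids):
        seen, dupes = set(), []
        for x in ids:
            if x in seen:
                dupes.append(x)
            seen.add(x)
        raise ValidationError(f"duplicate {what}: {sorted(set(dupes))[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """A nonnegative (observations x genes) expression matrix with string labels.

    Gene and row identifiers are whitespace-stripped on construction; matching
    elsewhere in the package is by exact string equality (no case folding).
    """

    values: np.ndarray
    row_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        self.row_ids = _check_unique(self.row_ids, "row identifiers")
        self.gene_ids = _check_unique(self.gene_ids, "gene identifiers")
        if self.values.shape != (len(self.row_ids), len(self.gene_ids)):
            raise ValidationError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.row_ids)} rows / {len(self.gene_ids)} genes"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if np.any(self.values < 0):
            r, g = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative expression at row {self.row_ids[r]!r}, "
                f"gene {self.gene_ids[g]!r}: {self.values[r, g]}"
            )

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, idx: np.ndarray) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            self.values[:, idx],
            list(self.row_ids),
            [self.gene_ids[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.gene_ids)


@dataclass
class SpatialDataset:
    """Spot-level expression plus 2-D/3-D coordinates (one row per spot)."""

    expr: ExpressionMatrix
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] not in (2, 3):
            raise ValidationError("coordinates must be |I| x 2 or |I| x 3")
        if self.coords.shape[0] != self.expr.n_rows:
            raise ValidationError(
                f"{self.coords.shape[0]} coordinate rows for {self.expr.n_rows} spots"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates must be finite")

    @property
    def spot_ids(self) -> list[str]:
        return self.expr.row_ids

    @property
    def n_spots(self) -> int:
        return self.expr.n_rows


@dataclass
class ReferenceData:
    """Annotated single-cell reference: expression plus one label per cell.

    ``labels`` is categorical; every category must contain at least one cell.
    """

    expr: ExpressionMatrix
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray([str(x).strip() for x in np.asarray(self.labels)])
        if self.labels.shape[0] != self.expr.n_rows:
            raise ValidationError(
                f"{self.labels.shape[0]} labels for {self.expr.n_rows} cells"
            )
        if self.labels.size == 0:
            raise ValidationError("reference has no cells")

    @property
    def categories(self) -> list[str]:
        # first-appearance order: deterministic and independent of lexical sorting
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return list(seen)


@dataclass
class TransferMap:
    """Nonnegative (sub-)population x spot abundance matrix.

    Column sums (spot sizes) are constrained to ``[1, capacity_i]`` per spot.
    """

    Y: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    capacity: np.ndarray

    # column-sum bound check tolerance; iterates sit exactly on the bounds
    _tol: float = field(default=1e-9, repr=False)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.row_ids = _check_unique(self.row_ids, "population identifiers")
        self.col_ids = _check_unique(self.col_ids, "spot identifiers")
        if self.Y.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValidationError("Y shape inconsistent with identifiers")
        self.capacity = np.broadcast_to(
            np.asarray(self.capacity, dtype=float), (len(self.col_ids),)
        ).copy()
        if self.Y.size:
            if np.any(self.Y < -self._tol):
                raise ValidationError("transfer map must be nonnegative")
            sums = self.Y.sum(axis=0)
            if np.any(sums < 1 - self._tol) or np.any(sums > self.capacity + self._tol):
                raise ValidationError(
                    "column sums must lie in [1, capacity] for every spot"
                )

    @property
    def spot_sizes(self) -> np.ndarray:
        return self.Y.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Spots x populations table with a trailing ``size`` column."""
        df = pd.DataFrame(self.Y.T, index=self.col_ids, columns=self.row_ids)
        df["size"] = self.spot_sizes
        df.index.name = "spot_id"
        return df


@dataclass
class AbundancePrior:
    """Expected abundance of each population, scaled to a total mass ``total_scale``."""

    r: np.ndarray
    categories: list[str]
    total_scale: float | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 1 or self.r.shape[0] != len(self.categories):
            raise ValidationError("prior length must match categories")
        if np.any(self.r < 0):
            raise ValidationError("prior abundances must be nonnegative")
        if self.r.sum() <= 0:
            raise ValidationError("prior abundances must not be all zero")
        if self.total_scale is not None:
            self.r = self.r * (float(self.total_scale) / self.r.sum())

    def scaled(self, total: float) -> "AbundancePrior":
        return AbundancePrior(self.r.copy(), list(self.categories), total_scale=total)
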