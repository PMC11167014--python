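"""Reading and writing the package's plain-text exchange formats.

Two expression formats are supported:

* dense delimited (CSV/TSV): header row of gene identifiers, first column of
  row identifiers;
* MatrixMarket coordinate triplets with sidecar label files (``<stem>.rows.txt``
  and ``<stem>.cols.txt`` next to the ``.mtx`` file, one identifier per line).

Coordinates are a delimited table with columns ``spot_id, x, y[, z]``, taken
as-is in the file's units.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .containers import (
    AbundancePrior,
    ExpressionMatrix,
    SpatialDataset,
    TransferMap,
    ValidationError,
)

__all__ = [
    "read_expression",
    "write_expression",
    "read_coords",
    "read_labels",
    "read_prior",
    "align_genes",
    "write_transfer_map",
    "read_transfer_map",
]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_expression(
    path: str | os.PathLike,
    fmt: str | None = None,
    row_labels: str | os.PathLike | None = None,
    col_labels: str | os.PathLike | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from dense delimited text or MatrixMarket.

    ``fmt`` is ``"dense"`` or ``"mtx"``; inferred from the extension when None.
    For MatrixMarket, sidecar label files default to ``<stem>.rows.txt`` /
    ``<stem>.cols.txt``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    if fmt is None:
        fmt = "mtx" if path.suffix.lower() == ".mtx" else "dense"

    if fmt == "mtx":
        rows_path = Path(row_labels) if row_labels else path.with_suffix(".rows.txt")
        cols_path = Path(col_labels) if col_labels else path.with_suffix(".cols.txt")
        for p, what in ((rows_path, "row"), (cols_path, "gene")):
            if not p.exists():
                raise FileNotFoundError(f"{what}-label sidecar file not found: {p}")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        row_ids = rows_path.read_text().split()
        gene_ids = cols_path.read_text().split()
        if mat.shape != (len(row_ids), len(gene_ids)):
            raise ValidationError(
                f"matrix shape {mat.shape} does not match "
                f"{len(row_ids)} row labels / {len(gene_ids)} gene labels"
            )
        return ExpressionMatrix(np.asarray(mat, dtype=float), row_ids, gene_ids)

    if fmt == "dense":
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
        return ExpressionMatrix(
            df.to_numpy(dtype=float),
            [str(x) for x in df.index],
            [str(x) for x in df.columns],
        )

    raise ValueError(f"unknown expression format: {fmt!r}")


def write_expression(X: ExpressionMatrix, path: str | os.PathLike) -> None:
    path = Path(path)
    X.to_frame().to_csv(path, sep=_sep_for(path))


def read_coords(path: str | os.PathLike) -> tuple[list[str], np.ndarray]:
    """Read a spot coordinate table; returns (spot ids, |I| x dim array)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"coordinate file not found: {path}")
    df = pd.read_csv(path, sep=_sep_for(path))
    cols = [c for c in ("x", "y", "z") if c in df.columns]
    if "spot_id" not in df.columns or len(cols) < 2:
        raise ValidationError(
            "coordinate table must have columns spot_id, x, y[, z]"
        )
    return [str(x) for x in df["spot_id"]], df[cols].to_numpy(dtype=float)


def read_labels(path: str | os.PathLike) -> tuple[list[str], np.ndarray]:
    """Read a two-column (cell_id, label) table; returns (cell ids, labels)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    df = pd.read_csv(path, sep=_sep_for(path))
    if df.shape[1] < 2:
        raise ValidationError("label table must have two columns: cell_id, label")
    return [str(x) for x in df.iloc[:, 0]], df.iloc[:, 1].astype(str).to_numpy()


def read_prior(path: str | os.PathLike) -> AbundancePrior:
    """Read a (category, abundance) table as an expected-abundance prior."""
    df = pd.read_csv(Path(path), sep=_sep_for(Path(path)))
    if df.shape[1] < 2:
        raise ValidationError("prior table must have two columns: category, abundance")
    return AbundancePrior(
        df.iloc[:, 1].to_numpy(dtype=float), [str(x) for x in df.iloc[:, 0]]
    )


def align_genes(
    ref: ExpressionMatrix, spatial: SpatialDataset | ExpressionMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Match genes between reference and spatial data by exact identifier.

    Returns ``(shared_idx, spatial_only_idx)``: integer indices into the
    *spatial* gene axis, in spatial order. The shared set is the gene universe
    for the expression-matching objectives; the full spatial set (shared plus
    spatial-only) feeds the spot-similarity weights.
    """
    sp_expr = spatial.expr if isinstance(spatial, SpatialDataset) else spatial
    ref_set = set(ref.gene_ids)
    shared = [i for i, g in enumerate(sp_expr.gene_ids) if g in ref_set]
    if not shared:
        raise ValidationError(
            "no genes shared between reference and spatial data; "
            "harmonize gene identifiers (exact string match after "
            "whitespace stripping is required)"
        )
    only = [i for i in range(sp_expr.n_genes) if i not in set(shared)]
    return np.asarray(shared, dtype=int), np.asarray(only, dtype=int)


def write_transfer_map(Y: TransferMap, path: str | os.PathLike) -> None:
    """Write spots x populations abundances plus a spot-size column."""
    path = Path(path)
    df = Y.to_frame()
    df.to_csv(path, sep=_sep_for(path), float_format="%.15g")


def read_transfer_map(path: str | os.PathLike, capacity: float | np.ndarray | None = None) -> TransferMap:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if "size" in df.columns:
        df = df.drop(columns="size")
    Y = df.to_numpy(dtype=float).T
    if capacity is None:
        capacity = np.maximum(1.0, Y.sum(axis=0)) if Y.size else 1.0
    return TransferMap(
        Y, [str(c) for c in df.columns], [str(i) for i in df.index], capacity
    )
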