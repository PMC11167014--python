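"""Reference centroid construction and within-population sub-clustering.

A categorical reference is summarized by one centroid (mean expression) per
population. Because a single centroid can misrepresent a heterogeneous
population, each population may additionally be partitioned into up to
``kappa`` sub-clusters by k-means; the optimizer then works at sub-cluster
resolution and results are collapsed back to populations afterwards.
Sub-clusters holding fewer than ``min_fraction`` of a population's cells are
treated as outliers and dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .containers import ReferenceData, TransferMap, ValidationError

__all__ = ["ReferenceProfiles", "compute_centroids", "subcluster", "collapse"]

DEFAULT_KAPPA = 10
DEFAULT_MIN_FRACTION = 0.01


@dataclass
class ReferenceProfiles:
    """Centroid matrix over (sub-)populations with parent bookkeeping."""

    X_R: np.ndarray            # |C'| x genes, row means of member cells
    row_ids: list[str]         # sub-cluster identifiers
    parent: dict[str, str]     # sub-cluster -> parent population
    member_counts: np.ndarray  # cells per sub-cluster
    gene_ids: list[str]
    kappa: int = 1

    def __post_init__(self) -> None:
        self.X_R = np.asarray(self.X_R, dtype=float)
        self.member_counts = np.asarray(self.member_counts, dtype=int)
        if len(self.row_ids) != self.X_R.shape[0]:
            raise ValidationError("profile rows inconsistent with identifiers")
        for rid in self.row_ids:
            if rid not in self.parent:
                raise ValidationError(f"sub-cluster {rid!r} has no parent population")
        if np.any(self.member_counts < 1):
            raise ValidationError("every sub-cluster needs at least one member cell")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for rid in self.row_ids:
            seen.setdefault(self.parent[rid], None)
        return list(seen)

    def restrict_genes(self, idx: np.ndarray, gene_ids: list[str]) -> "ReferenceProfiles":
        return ReferenceProfiles(
            self.X_R[:, np.asarray(idx)],
            list(self.row_ids),
            dict(self.parent),
            self.member_counts.copy(),
            list(gene_ids),
            self.kappa,
        )


def compute_centroids(
    ref: ReferenceData, genes: np.ndarray | None = None
) -> ReferenceProfiles:
    """Mean expression per population (``kappa=1``), optionally gene-restricted.

    ``genes`` is an integer index into the reference gene axis; None keeps all.
    """
    values = ref.expr.values
    gene_ids = ref.expr.gene_ids
    if genes is not None:
        genes = np.asarray(genes)
        values = values[:, genes]
        gene_ids = [ref.expr.gene_ids[i] for i in genes]
    cats = ref.categories
    X_R = np.empty((len(cats), values.shape[1]))
    counts = np.empty(len(cats), dtype=int)
    for k, c in enumerate(cats):
        mask = ref.labels == c
        counts[k] = int(mask.sum())
        X_R[k] = values[mask].mean(axis=0)
        if np.all(X_R[k] == 0):
            warnings.warn(
                f"population {c!r} has an all-zero centroid on the selected "
                "genes; its cosine distances are degenerate",
                stacklevel=2,
            )
    return ReferenceProfiles(
        X_R, list(cats), {c: c for c in cats}, counts, gene_ids, kappa=1
    )


def subcluster(
    ref: ReferenceData,
    kappa: int = DEFAULT_KAPPA,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    seed: int = 0,
    log_transform: bool = False,
) -> ReferenceProfiles:
    """Partition each population into up to ``kappa`` k-means sub-clusters.

    Clustering uses all reference genes (shared and reference-exclusive);
    restriction to the shared gene set happens later, at modeling time.
    Populations smaller than ``kappa`` get one cluster per cell. Sub-clusters
    with fewer than ``min_fraction`` of their population's cells are dropped.
    With ``kappa=1`` this reduces exactly to :func:`compute_centroids`.
    """
    if kappa < 1:
        raise ValidationError("kappa must be >= 1")
    if not 0 <= min_fraction < 1:
        raise ValidationError("min_fraction must lie in [0, 1)")
    if kappa == 1:
        return compute_centroids(ref)

    rows: list[np.ndarray] = []
    row_ids: list[str] = []
    parent: dict[str, str] = {}
    counts: list[int] = []
    values = ref.expr.values
    feats = np.log1p(values) if log_transform else values
    for c in ref.categories:
        mask = ref.labels == c
        pop_feats = feats[mask]
        pop_values = values[mask]
        n_cells = pop_feats.shape[0]
        k = min(kappa, n_cells)
        if k == 1:
            labels = np.zeros(n_cells, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=10, random_state=seed)
            labels = km.fit_predict(pop_feats)
        keep_min = min_fraction * n_cells
        for j in range(k):
            members = labels == j
            m = int(members.sum())
            if m == 0 or m < keep_min:
                continue
            rid = f"{c}::{len([r for r in row_ids if parent.get(r) == c])}"
            rows.append(pop_values[members].mean(axis=0))
            row_ids.append(rid)
            parent[rid] = c
            counts.append(m)
    return ReferenceProfiles(
        np.vstack(rows),
        row_ids,
        parent,
        np.asarray(counts),
        list(ref.expr.gene_ids),
        kappa=kappa,
    )


def collapse(Y: TransferMap, parent: dict[str, str]) -> TransferMap:
    """Aggregate a sub-cluster-level transfer map to population level.

    Each population row is the sum of its sub-cluster rows; column sums (spot
    sizes) are unchanged.
    """
    for rid in Y.row_ids:
        if rid not in parent:
            raise ValidationError(f"row {rid!r} has no parent population")
    pops: dict[str, None] = {}
    for rid in Y.row_ids:
        pops.setdefault(parent[rid], None)
    pop_list = list(pops)
    out = np.zeros((len(pop_list), Y.Y.shape[1]))
    pop_index = {c: k for k, c in enumerate(pop_list)}
    for r, rid in enumerate(Y.row_ids):
        out[pop_index[parent[rid]]] += Y.Y[r]
    return TransferMap(out, pop_list, list(Y.col_ids), Y.capacity)
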