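"""Synthetic benchmark generator.

Emulates the structure of imaging-based single-cell-resolution spatial data
with a matched annotated reference: distinct per-population expression
programs with marker genes, optional within-population subtypes (to exercise
sub-clustering), spatially contiguous cell-type regions, grid pooling into
multicell tiles with known compositions and cell counts, multiplicative
uniform expression noise, and prefix gene subsetting to mimic a limited
spatial gene panel.

Expression is Poisson around population programs. A program is a shared
baseline (uniform across genes) with each population's marker genes elevated
10-fold; markers are striped across the gene index (gene g marks population
g mod K) so that any prefix panel contains markers of every population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix, ReferenceData, SpatialDataset

__all__ = [
    "SimulationSpec",
    "SyntheticTruth",
    "make_reference",
    "make_highres_spatial",
    "pool_to_lowres",
    "add_noise",
    "subset_genes",
]

MARKER_FOLD = 10.0
SUBTYPE_FOLD = 8.0
SUBTYPE_MARKERS = 3
PROGRAM_SCALE = 5.0  # mean counts per baseline gene; markers average 10x this


@dataclass
class SimulationSpec:
    """Generation parameters for one synthetic benchmark instance."""

    num_populations: int = 10
    genes_total: int = 100
    markers_per_population: int = 5
    cells_per_population: int = 200
    within_pop_subtypes: int = 1
    spatial_layout: str = "regions"       # or "random"
    grid_side: int = 45                   # grid_side^2 single-cell spots
    tile_length: float = 3.2              # pooling tile edge, in grid units
    noise_phi: float = 0.0
    shared_gene_count: int | None = None  # spatial panel size; None = all genes
    dispersion: float = 0.0               # gamma over-dispersion of Poisson rates
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "num_populations",
            "genes_total",
            "markers_per_population",
            "cells_per_population",
            "within_pop_subtypes",
            "grid_side",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.tile_length <= 0:
            raise ValueError("tile_length must be positive")
        if not 0 <= self.noise_phi <= 1:
            raise ValueError("noise_phi must lie in [0, 1]")
        if self.spatial_layout not in ("regions", "random"):
            raise ValueError("spatial_layout must be 'regions' or 'random'")
        needed = self.num_populations * self.markers_per_population
        if self.within_pop_subtypes > 1:
            needed += self.num_populations * self.within_pop_subtypes * SUBTYPE_MARKERS
        if self.genes_total < needed:
            raise ValueError(
                f"genes_total={self.genes_total} too small for the marker "
                f"layout (needs >= {needed})"
            )

    @property
    def categories(self) -> list[str]:
        return [f"pop{k}" for k in range(self.num_populations)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{j}" for j in range(self.genes_total)]


@dataclass
class SyntheticTruth:
    """Ground-truth bookkeeping for a generated instance.

    High-resolution: ``labels`` (and ``subtype_labels``) per spot. After
    pooling: ``composition`` holds per-tile member-label counts (populations x
    tiles) and ``cell_counts`` the number of pooled cells per tile.
    """

    categories: list[str]
    labels: np.ndarray | None = None
    subtype_labels: np.ndarray | None = None
    composition: np.ndarray | None = None
    cell_counts: np.ndarray | None = None

    @property
    def relative_composition(self) -> np.ndarray:
        if self.composition is None:
            raise ValueError("no pooled composition recorded")
        return self.composition / self.composition.sum(axis=0)


def _programs(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    """(populations * subtypes) x genes mean-expression programs."""
    K, G, s = spec.num_populations, spec.genes_total, spec.within_pop_subtypes
    baseline = rng.uniform(0.5, 1.5, size=G) * PROGRAM_SCALE
    progs = np.tile(baseline, (K * s, 1))
    n_marked = K * spec.markers_per_population
    for g in range(n_marked):
        pop = g % K
        for sub in range(s):
            progs[pop * s + sub, g] *= MARKER_FOLD
    if s > 1:
        base = n_marked
        for pop in range(K):
            for sub in range(s):
                lo = base + (pop * s + sub) * SUBTYPE_MARKERS
                progs[pop * s + sub, lo : lo + SUBTYPE_MARKERS] *= SUBTYPE_FOLD
    return progs


def _draw_counts(
    progs_rows: np.ndarray, spec: SimulationSpec, rng: np.random.Generator
) -> np.ndarray:
    rates = progs_rows
    if spec.dispersion > 0:
        shape = 1.0 / spec.dispersion
        rates = rates * rng.gamma(shape, 1.0 / shape, size=rates.shape)
    return rng.poisson(rates).astype(float)


def make_reference(spec: SimulationSpec) -> ReferenceData:
    """Annotated reference: ``cells_per_population`` Poisson draws per population.

    With ``within_pop_subtypes > 1`` cells are split evenly across subtype
    programs, but the recorded label remains the parent population —
    heterogeneity is latent, as in real annotations.
    """
    rng = np.random.default_rng(spec.seed)
    progs = _programs(spec, rng)
    K, s = spec.num_populations, spec.within_pop_subtypes
    rows, labels = [], []
    for pop in range(K):
        subs = rng.integers(0, s, size=spec.cells_per_population)
        rows.append(_draw_counts(progs[pop * s + subs], spec, rng))
        labels.extend([f"pop{pop}"] * spec.cells_per_population)
    values = np.vstack(rows)
    cell_ids = [f"cell{i}" for i in range(values.shape[0])]
    return ReferenceData(
        ExpressionMatrix(values, cell_ids, spec.gene_ids), np.asarray(labels)
    )


def _assign_regions(
    coords: np.ndarray, spec: SimulationSpec, rng: np.random.Generator
) -> np.ndarray:
    """Contiguous cell-type regions: Voronoi cells of random anchors."""
    K = spec.num_populations
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    anchors = rng.uniform(lo, hi, size=(K, coords.shape[1]))
    d2 = ((coords[:, None, :] - anchors[None, :, :]) ** 2).sum(-1)
    return d2.argmin(axis=1)


def make_highres_spatial(
    spec: SimulationSpec,
) -> tuple[SpatialDataset, SyntheticTruth]:
    """Single-cell-resolution spatial dataset on a ``grid_side``-square grid.

    Cell types form contiguous Voronoi regions ("regions" layout) or are
    assigned uniformly at random ("random"). Each spot's expression is a fresh
    Poisson draw from its (sub)population program. Uses a generation stream
    independent of :func:`make_reference` (offset seed) so spatial cells are
    not reference cells; the programs themselves are shared via ``spec.seed``.
    """
    rng_prog = np.random.default_rng(spec.seed)
    progs = _programs(spec, rng_prog)
    rng = np.random.default_rng(spec.seed + 1_000_003)

    side = spec.grid_side
    xs, ys = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    n = coords.shape[0]

    if spec.spatial_layout == "regions":
        pop_idx = _assign_regions(coords, spec, rng)
    else:
        pop_idx = rng.integers(0, spec.num_populations, size=n)
    s = spec.within_pop_subtypes
    sub_idx = rng.integers(0, s, size=n)
    values = _draw_counts(progs[pop_idx * s + sub_idx], spec, rng)

    panel = spec.shared_gene_count or spec.genes_total
    spot_ids = [f"spot{i}" for i in range(n)]
    dataset = SpatialDataset(
        ExpressionMatrix(values, spot_ids, spec.gene_ids), coords
    )
    if panel < spec.genes_total:
        dataset = subset_genes(dataset, panel)
    truth = SyntheticTruth(
        categories=spec.categories,
        labels=np.asarray([f"pop{p}" for p in pop_idx]),
        subtype_labels=sub_idx.copy(),
    )
    return dataset, truth


def pool_to_lowres(
    highres: SpatialDataset, truth: SyntheticTruth, tile_length: float
) -> tuple[SpatialDataset, SyntheticTruth]:
    """Aggregate single-cell spots into square tiles of edge ``tile_length``.

    Tile expression is the sum over member cells; tile coordinates are tile
    centers; empty tiles are dropped. The returned truth records per-tile
    label counts and cell counts.
    """
    if tile_length <= 0:
        raise ValueError("tile_length must be positive")
    if truth.labels is None:
        raise ValueError("high-resolution truth labels are required for pooling")
    coords = highres.coords
    tile_idx = np.floor(coords / tile_length).astype(int)
    keys, inverse = np.unique(tile_idx, axis=0, return_inverse=True)
    n_tiles = keys.shape[0]
    G = highres.expr.n_genes

    expr = np.zeros((n_tiles, G))
    np.add.at(expr, inverse, highres.expr.values)

    cats = truth.categories
    pos = {c: k for k, c in enumerate(cats)}
    comp = np.zeros((len(cats), n_tiles))
    lab_idx = np.asarray([pos[str(lab)] for lab in truth.labels])
    np.add.at(comp, (lab_idx, inverse), 1.0)

    centers = (keys + 0.5) * tile_length
    tile_ids = [f"tile{i}" for i in range(n_tiles)]
    dataset = SpatialDataset(
        ExpressionMatrix(expr, tile_ids, list(highres.expr.gene_ids)), centers
    )
    pooled_truth = SyntheticTruth(
        categories=cats,
        composition=comp,
        cell_counts=comp.sum(axis=0),
    )
    return dataset, pooled_truth


def add_noise(spatial: SpatialDataset, phi: float, seed: int = 0) -> SpatialDataset:
    """Multiply every entry by an independent uniform factor in [1-phi, 1+phi]."""
    if not 0 <= phi <= 1:
        raise ValueError("phi must lie in [0, 1] (phi > 1 would create negatives)")
    if phi == 0:
        return spatial
    rng = np.random.default_rng(seed)
    factors = rng.uniform(1.0 - phi, 1.0 + phi, size=spatial.expr.values.shape)
    return SpatialDataset(
        ExpressionMatrix(
            spatial.expr.values * factors,
            list(spatial.expr.row_ids),
            list(spatial.expr.gene_ids),
        ),
        spatial.coords,
    )


def subset_genes(spatial: SpatialDataset, count: int) -> SpatialDataset:
    """Keep the first ``count`` genes in stored order (limited-panel emulation)."""
    if not 1 <= count <= spatial.expr.n_genes:
        raise ValueError(
            f"count must lie in [1, {spatial.expr.n_genes}], got {count}"
        )
    return SpatialDataset(
        spatial.expr.subset_genes(np.arange(count)), spatial.coords
    )
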