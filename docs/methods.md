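# Methods

## Model

`spotmap` estimates a transfer matrix **Y** ∈ R₊^(|C′|×|I|) from reference
(sub-)populations C′ to spatial spots I by minimizing a weighted sum of five
penalties, subject to per-spot mass bounds `1 ≤ Σ_c Y_ci ≤ n_i`:

1. **Spot expression match.** Each spot's shared-gene profile should match
   the profile transferred to it, `Σ_c Y_ci X^R_c`. Dissimilarity is
   `d_cos(a,b) = √(1 − cos(a,b))`: unlike plain cosine dissimilarity this is
   a metric, and it is scale-invariant, so neither platform sensitivity nor
   spot size biases the match. A sparsity parameter θ blends this mixture
   distance with the linear form `(1/n̄_i) Σ_c Y_ci d_cos(X^S_i, X^R_c)`;
   the two coincide exactly when a column of Y is concentrated on a single
   category, and the linear form drives solutions toward such pure columns.
   θ = 0 recovers the pure mixture match. n̄_i is fixed to the capacity n_i.
2. **Population expression match** (weight λ_C). The centroid of population c
   should match the expression mass Y assigns to it, `Σ_i Y_ci X^S_i`. By
   scale invariance the normalization 1/ρ_c drops out.
3. **Gene map match** (weight λ_G). The spatial map of each shared gene
   should match its transferred map `(YᵀX^R)_:,g`.
4. **Local spatial coherence** (weight λ_S). For pairs P of spots that are
   both adjacent (‖x_i − x_j‖ ≤ d̄) and transcriptionally similar (cosine
   similarity w_ij ≥ w̄ over the *full* spatial gene panel, so genes absent
   from the reference still inform neighborhood structure), the base-2
   Jensen-Shannon divergence between raw abundance columns is penalized with
   weight w_ij. No global spatial autocorrelation is assumed — only pairs
   that look alike are tied together. d_S is convex in Y and costs O(|P|).
5. **Expected abundance** (weight λ_A, optional). JS divergence between total
   transferred mass per population, ρ, and a prior **r** scaled to total mass
   N = n|I|. With sub-clustering, ρ aggregates sub-cluster rows to their
   parent populations first.

JS divergences are applied to **unnormalized** nonnegative vectors with
base-2 logarithms and the 0·log 0 = 0 convention. This choice (rather than
normalizing columns first) makes the spatial term bounded by n|P|, which is
what the automatic weight rule for λ_S relies on; a normalize-first variant
would change the meaning of λ_S. Mass differences between neighboring
columns are then penalized alongside compositional differences, which is
intended: neighboring similar spots should hold similar amounts of similar
cells.

## Reference heterogeneity

A single centroid can misrepresent a heterogeneous population, so each
population may be partitioned into up to κ sub-clusters (default κ = 10 when
sub-clustering is requested; the pipeline default is κ = 1, see below) by
k-means (10 restarts, fixed seed — chosen for determinism and speed; any
unsupervised partition would do). Clustering uses all reference genes, not
just shared ones; centroids are restricted to shared genes only for
modeling. Sub-clusters holding under `min_fraction` (default 1%) of their
population are dropped as outliers. The solver works at sub-cluster
resolution and the result is collapsed by summing sibling rows, which leaves
spot sizes unchanged. Singleton sub-clusters (κ = population size) are
supported but not default: transferring individual cells is expensive and
prone to over-fitting.

## Automatic parameter rules

All hyperparameters derive from data dimensions so the terms contribute on
comparable scales (the spot term ranges over [0, |I|]; the population, gene,
spatial, and abundance terms are bounded by |C′|, |G|, n|P|, and ~N):

| parameter | single-cell spots ("high") | multicell spots ("low") |
|---|---|---|
| λ_C | 0.5·\|I\|/\|C′\| | 0.6·\|I\|/\|C′\| |
| λ_G | 1.25·\|I\|/\|G\| | 1.5·\|I\|/\|G\| |
| λ_S | 0.5·\|I\|/\|P\| | 0.4·\|I\|/(n\|P\|) |
| λ_A | 1/n if prior given, else 0 | same |
| θ | 0.6 | 0.4 |
| n | 1 | platform (Visium 20, ST 200), override, or N/\|I\| |

λ_C and λ_G use the number of rows actually optimized (|C′|, i.e. after
sub-clustering). No internal estimator of the total cell count N is
provided; for platforms other than Visium/ST the user supplies n or N.

Spatial thresholds: d̄ is the 90th percentile (linear interpolation between
order statistics — fixed for cross-platform reproducibility) of each spot's
distances to its 8 nearest neighbors pooled over all spots (8|I| values,
mirroring the 8 adjacent tiles of a 2-D grid; duplicates contribute true
zero distances; with < 9 spots, the maximum pairwise distance is used). w̄ is
the larger of 0.6 and the smallest value keeping |P| ≤ |I|, so the spatial
term stays linear in |I|; ties at the cutoff are all retained, since the
cutoff is defined on the similarity value, not the pair count.

## Solver

Frank-Wolfe on the product of per-spot polytopes
`{y ≥ 0, 1 ≤ Σ y ≤ n_i}`. The linearized problem decomposes per spot with a
closed-form vertex solution: all mass on the category ĉ with the smallest
gradient coefficient, at level n_i if that coefficient is negative, else 1
(ties broken to the lowest index for determinism). Steps are convex
combinations, so iterates remain feasible exactly.

Loop control (the defaults are this package's own choices): uniform start
`Y_ci = 1/|C′|`; backtracking Armijo line search on γ ∈ (0,1] (c₁ = 10⁻⁴,
halving) with a diminishing-step alternative γ_t = 2/(t+2); stop on relative
objective change < 10⁻⁵, a vanishing Frank-Wolfe gap (first-order
optimality — with all λ = 0, θ = 1, n = 1 the objective is linear and the
first atom is already the exact binary nearest-centroid solution), or 200
iterations.

Numerical safeguards, used in the gradient only (reported objective values
are unsmoothed): the derivative of √(1−cos) is unbounded as cos → 1, so
1 − cos is clamped at 10⁻⁹ inside the differentiated square root; JS log
arguments are floored at 10⁻¹²; both effects vanish as the floors go to 0.
Degenerate inputs: an all-zero vector is at cosine distance 1 from any
nonzero vector and 0 from another all-zero vector (bounded, no NaNs), with
zero gradient; all-zero spots join no spatial pair (cosine similarity
undefined) and trigger a warning. The JS gradient uses the closed form
∂JS(p,q)/∂p_k = ½ log₂(2p_k/(p_k+q_k)).

Expression is consumed as provided — counts or continuous intensities, no
mandatory normalization (scale invariance of d_cos makes global scaling
irrelevant); an optional per-row total-count scaling and an optional log
transform for the k-means step are available as explicit knobs.

## Synthetic benchmark

The generator emulates the structure of an imaging-based single-cell-
resolution spatial experiment with a matched annotated reference. Defaults:
10 populations, 100 genes, 5 marker genes per population elevated 10-fold
over a shared uniform baseline (markers striped across the gene index so any
prefix panel contains markers of every population), 200 reference cells per
population, Poisson counts around the programs (an over-dispersion knob adds
gamma rate mixing), cell types arranged in contiguous Voronoi regions on a
45×45 unit grid (2025 single-cell spots). Multicell data is made by summing
cells within square tiles (default edge 3.2 grid units ≈ 200 tiles of ≈ 10
cells, the nonempty-tile convention, coordinates at tile centers), technical
noise by multiplying each entry by an independent uniform factor in
[1−φ, 1+φ], and limited panels by keeping a prefix of the gene index.
Optional latent subtypes within populations (extra 8-fold marker blocks)
exercise κ sub-clustering; because the default reference is generated
homogeneous, the pipeline examples and benchmark runs use κ = 1, which is
the appropriate model for that reference.

What the generator does **not** emulate: platform-specific dropout and
segmentation errors, mismatched reference/spatial tissue composition,
ambient contamination, batch effects, or continuous cell-state gradients.
Passing benchmarks therefore demonstrates correctness of the optimization
and the recoverability of well-separated populations under multiplicative
noise and pooling — not performance on real tissue.

Benchmark problem sizes (2025 spots, ~200 tiles, 100 genes, 5 replicate
seeds) were chosen as the smallest instances that exercise every model term
with stable statistics; all benchmark quantities are recomputed from scratch
by `scripts/acceptance.py`.

## Evaluation metrics

Accuracy (fraction of correctly labeled spots), Brier score
`|I|⁻¹ Σ_i Σ_c (Y_ci − P_ci)²` on membership probabilities, and a spatially
smoothed JS divergence: the one-hot truth is smoothed with a Gaussian kernel
`K_ij = exp(−‖x_i−x_j‖²/2σ²)` (self term included; σ defaults to 0.5·d̄),
and the mean base-2 JS divergence between predicted and smoothed columns is
reported. For multicell spots, per-spot JS between estimated and true
relative compositions applies directly.

## Known limitations

- The objective is non-convex (the spot/population/gene terms are
  quasi-convex at best), so Frank-Wolfe reaches a stationary point, not a
  certified global optimum; results are deterministic given the seed.
- Spot capacity is a single n per dataset, not per-spot estimates.
- Gene matching is exact string identity after whitespace stripping — no
  case folding or alias resolution, by design: silent mismatches are worse
  than an explicit error.
- The abundance prior requires population-level categories; priors over
  sub-clusters are not supported (sub-cluster masses aggregate to parents).
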