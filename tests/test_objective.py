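import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spotmap import ModelData, ObjectiveWeights, cosine_metric, js_divergence, total_objective
from spotmap.objective import (
    gradient,
    term_abundance,
    term_genes,
    term_populations,
    term_spatial,
    term_spots,
)
from spotmap.pairs import SpatialPairSet

from conftest import random_instance


# ---------------------------------------------------------------------------
# independent naive oracles


def naive_cosdist(a, b):
    na = math.sqrt(sum(x * x for x in a))
    nb = math.sqrt(sum(x * x for x in b))
    if na == 0 and nb == 0:
        return 0.0
    if na == 0 or nb == 0:
        return 1.0
    s = sum(x * y for x, y in zip(a, b)) / (na * nb)
    return math.sqrt(max(0.0, 1.0 - min(s, 1.0)))


def naive_js(p, q):
    total = 0.0
    for pj, qj in zip(p, q):
        m = 0.5 * (pj + qj)
        if pj > 0:
            total += 0.5 * pj * math.log2(pj / m)
        if qj > 0:
            total += 0.5 * qj * math.log2(qj / m)
    return total


def naive_term_spots(Y, X_S, X_R, theta, nbar):
    n_spots = X_S.shape[0]
    total = 0.0
    for i in range(n_spots):
        mixed = [sum(Y[c, i] * X_R[c, g] for c in range(X_R.shape[0])) for g in range(X_R.shape[1])]
        total += (1 - theta) * naive_cosdist(X_S[i], mixed)
        total += (theta / nbar) * sum(
            Y[c, i] * naive_cosdist(X_S[i], X_R[c]) for c in range(X_R.shape[0])
        )
    return total


def naive_term_populations(Y, X_S, X_R):
    total = 0.0
    for c in range(X_R.shape[0]):
        mass = [sum(Y[c, i] * X_S[i, g] for i in range(X_S.shape[0])) for g in range(X_S.shape[1])]
        total += naive_cosdist(X_R[c], mass)
    return total


def naive_term_genes(Y, X_S, X_R):
    total = 0.0
    for g in range(X_S.shape[1]):
        mapped = [sum(Y[c, i] * X_R[c, g] for c in range(X_R.shape[0])) for i in range(X_S.shape[0])]
        total += naive_cosdist(X_S[:, g], mapped)
    return total


pos_vec = st.lists(st.floats(1e-3, 1e3), min_size=2, max_size=6)


# ---------------------------------------------------------------------------


class TestCosineMetric:
    def test_identity_and_collinearity(self):
        assert cosine_metric([2, 1], [2, 1]) == 0.0
        assert cosine_metric([1, 2], [3, 6]) == pytest.approx(0.0, abs=1e-7)

    def test_orthogonal_vectors_at_maximal_distance(self):
        assert cosine_metric([1, 0], [0, 1]) == 1.0

    def test_degenerate_zero_vector_policy(self):
        assert cosine_metric([0, 0], [1, 2]) == 1.0
        assert cosine_metric([0, 0], [0, 0]) == 0.0

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(pos_vec)
    def test_scale_invariance(self, v):
        assert cosine_metric(v, [3.7 * x for x in v]) == pytest.approx(0.0, abs=1e-6)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(pos_vec, st.integers(0, 10**6))
    def test_symmetry(self, v, seed):
        w = np.random.default_rng(seed).uniform(1e-3, 1e3, len(v))
        assert cosine_metric(v, w) == pytest.approx(cosine_metric(w, v), rel=1e-12)

    def test_triangle_inequality_bulk(self, rng):
        a, b, c = rng.uniform(1e-3, 1e3, (3, 10_000, 5))
        dab = np.array([cosine_metric(x, y) for x, y in zip(a[:500], b[:500])])
        # vectorized check on the full 1e4 set
        def d(u, v):
            s = (u * v).sum(1) / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
            return np.sqrt(np.clip(1 - s, 0, None))

        assert np.all(d(a, c) <= d(a, b) + d(b, c) + 1e-12)
        np.testing.assert_allclose(dab, d(a[:500], b[:500]), rtol=1e-12)


class TestJSDivergence:
    def test_identical_inputs_zero(self, rng):
        p = rng.uniform(0, 5, 6)
        assert js_divergence(p, p) == 0.0

    def test_disjoint_unit_masses_one_bit(self):
        assert js_divergence([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_disjoint_mass_m_vectors_equal_m(self, rng):
        m = 3.7
        p = np.array([m, 0.0, 0.0])
        q = np.array([0.0, m / 2, m / 2])
        assert js_divergence(p, q) == pytest.approx(m)
        assert js_divergence(p, q) == pytest.approx(naive_js(p, q))

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(0, 10**6))
    def test_symmetry_nonnegativity_and_range(self, seed):
        r = np.random.default_rng(seed)
        p, q = r.uniform(0, 1, (2, 5))
        p, q = p / p.sum(), q / q.sum()
        v = js_divergence(p, q)
        assert v == pytest.approx(js_divergence(q, p), rel=1e-12)
        assert 0.0 <= v <= 1.0 + 1e-12

    def test_matches_naive_summation(self, rng):
        p, q = rng.uniform(0, 4, (2, 8))
        assert js_divergence(p, q) == pytest.approx(naive_js(p, q), rel=1e-12)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            js_divergence([-1, 2], [1, 1])


class TestTerms:
    def test_spot_term_zero_for_exact_onehot_match(self, rng):
        X_R = rng.uniform(0.5, 3, (3, 6))
        X_S = X_R[[0, 2, 1]]
        Y = np.zeros((3, 3))
        Y[[0, 2, 1], [0, 1, 2]] = 1.0
        assert term_spots(Y, X_S, X_R, theta=0.0) == pytest.approx(0.0, abs=1e-7)

    def test_theta_one_reduces_to_linear_form(self, rng):
        X_R = rng.uniform(0.5, 3, (4, 5))
        X_S = rng.uniform(0.5, 3, (1, 5))
        Y = np.zeros((4, 1))
        Y[2, 0] = 1.0
        nbar = 3.0
        expected = cosine_metric(X_S[0], X_R[2]) / nbar
        assert term_spots(Y, X_S, X_R, theta=1.0, nbar=nbar) == pytest.approx(expected)

    def test_theta_zero_equals_pure_mixture_distance(self, rng):
        data, weights, Y = random_instance(rng)
        v0 = term_spots(Y, data.X_S, data.X_R, theta=0.0, nbar=5.0)
        naive = naive_term_spots(Y, data.X_S, data.X_R, 0.0, 5.0)
        assert v0 == pytest.approx(naive, abs=1e-10)

    def test_binary_Y_makes_both_branches_coincide(self, rng):
        """For one-hot columns scaled to nbar, the mixture distance equals the
        nbar-normalized linear form, so theta drops out."""
        X_R = rng.uniform(0.5, 3, (4, 6))
        X_S = rng.uniform(0.5, 3, (5, 6))
        nbar = 3.0
        Y = np.zeros((4, 5))
        Y[rng.integers(0, 4, 5), np.arange(5)] = nbar
        v_a = term_spots(Y, X_S, X_R, theta=0.0, nbar=nbar)
        v_b = term_spots(Y, X_S, X_R, theta=1.0, nbar=nbar)
        assert v_a == pytest.approx(v_b, rel=1e-10)

    def test_population_term_scale_invariant_in_rows(self, rng):
        data, _, Y = random_instance(rng)
        v = term_populations(Y, data.X_S, data.X_R)
        Y2 = Y.copy()
        Y2[1] *= 7.3
        assert term_populations(Y2, data.X_S, data.X_R) == pytest.approx(v, rel=1e-9)

    def test_population_term_zero_for_proportional_profiles(self, rng):
        X_S = rng.uniform(0.5, 2, (1, 5))
        X_R = 2.5 * X_S
        assert term_populations(np.array([[1.0]]), X_S, X_R) == pytest.approx(0.0, abs=1e-7)

    @pytest.mark.parametrize("term,naive", [
        (term_spots, naive_term_spots),
        (term_populations, naive_term_populations),
        (term_genes, naive_term_genes),
    ])
    def test_terms_match_naive_loops(self, rng, term, naive):
        for _ in range(5):
            data, weights, Y = random_instance(rng, n_spots=rng.integers(5, 20))
            if term is term_spots:
                got = term(Y, data.X_S, data.X_R, weights.theta, weights.nbar)
                want = naive(Y, data.X_S, data.X_R, weights.theta, weights.nbar)
            else:
                got = term(Y, data.X_S, data.X_R)
                want = naive(Y, data.X_S, data.X_R)
            assert got == pytest.approx(want, abs=1e-10)

    def test_gene_term_zero_when_marker_mapped_correctly(self):
        # one gene expressed only by population 0; Y places pop 0 exactly there
        X_R = np.array([[5.0, 1.0], [0.0, 1.0]])
        X_S = np.array([[5.0, 1.0], [0.0, 1.0]])
        Y = np.eye(2)
        assert term_genes(Y, X_S, X_R) == pytest.approx(0.0, abs=1e-7)

    def test_spatial_term_zero_for_identical_columns(self, rng):
        pairs = SpatialPairSet(np.array([[0, 1], [1, 2]]), np.array([1.0, 0.8]), 1.0, 0.6)
        Y = np.tile(rng.uniform(0.1, 1, (4, 1)), (1, 3))
        assert term_spatial(Y, pairs) == 0.0

    def test_spatial_term_disjoint_unit_pair(self):
        pairs = SpatialPairSet(np.array([[0, 1]]), np.array([1.0]), 1.0, 0.6)
        Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert term_spatial(Y, pairs) == pytest.approx(1.0)

    def test_spatial_term_attains_upper_bound(self, rng):
        """Columns of mass n with disjoint support across every pair: d_S = n|P|."""
        n = 4.0
        pairs = SpatialPairSet(np.array([[0, 1], [2, 3]]), np.array([1.0, 1.0]), 1.0, 0.6)
        Y = np.zeros((2, 4))
        Y[0, [0, 2]] = n
        Y[1, [1, 3]] = n
        assert term_spatial(Y, pairs) == pytest.approx(n * 2)

    def test_spatial_term_midpoint_convexity(self, rng):
        data, _, Y1 = random_instance(rng)
        _, _, Y2 = random_instance(rng)
        mid = 0.5 * (Y1 + Y2)
        lhs = term_spatial(mid, data.pairs)
        rhs = 0.5 * term_spatial(Y1, data.pairs) + 0.5 * term_spatial(Y2, data.pairs)
        assert lhs <= rhs + 1e-12

    def test_abundance_zero_when_matching_prior(self, rng):
        Y = rng.uniform(0.1, 1, (3, 6))
        r = Y.sum(axis=1)
        assert term_abundance(Y, r) == 0.0

    def test_abundance_invariant_to_subcluster_permutation(self, rng):
        Y = rng.uniform(0.1, 1, (4, 6))
        parent = np.array([0, 0, 1, 1])
        r = rng.uniform(1, 3, 2)
        v1 = term_abundance(Y, r, parent)
        Y2 = Y.copy()
        Y2[[0, 1]] = Y2[[1, 0]]  # swap mass among sub-clusters of population 0
        assert term_abundance(Y2, r, parent) == pytest.approx(v1, rel=1e-12)

    def test_abundance_matches_naive_aggregation(self, rng):
        Y = rng.uniform(0.1, 1, (4, 5))
        parent = np.array([0, 1, 0, 1])
        r = rng.uniform(1, 3, 2)
        rho = [Y[[0, 2]].sum(), Y[[1, 3]].sum()]
        assert term_abundance(Y, r, parent) == pytest.approx(naive_js(rho, r), rel=1e-10)

    def test_all_zero_prior_rejected(self, rng):
        with pytest.raises(ValueError, match="all zero"):
            term_abundance(rng.uniform(0, 1, (2, 3)), np.zeros(2))


class TestTotalObjective:
    def test_zero_weights_leave_only_spot_term(self, rng):
        data, _, Y = random_instance(rng)
        w0 = ObjectiveWeights(theta=0.0, nbar=4.0)
        bk = total_objective(Y, data, w0)
        assert bk.total == pytest.approx(term_spots(Y, data.X_S, data.X_R, 0.0))

    def test_linearity_in_lambda(self, rng):
        data, weights, Y = random_instance(rng)
        bk = total_objective(Y, data, weights)
        half = ObjectiveWeights(
            lambda_C=weights.lambda_C / 2,
            lambda_G=weights.lambda_G / 2,
            lambda_S=weights.lambda_S / 2,
            lambda_A=weights.lambda_A / 2,
            theta=weights.theta,
            nbar=weights.nbar,
        )
        bk_half = total_objective(Y, data, half)
        tail = bk.total - bk.term_spots
        assert bk_half.total - bk_half.term_spots == pytest.approx(tail / 2, rel=1e-10)

    def test_breakdown_composes(self, rng):
        data, weights, Y = random_instance(rng)
        bk = total_objective(Y, data, weights)
        recomposed = (
            bk.term_spots
            + weights.lambda_C * bk.term_pops
            + weights.lambda_G * bk.term_genes
            + weights.lambda_S * bk.term_spatial
            + weights.lambda_A * bk.term_abund
        )
        assert bk.total == pytest.approx(recomposed, rel=1e-12)

    def test_scale_invariance_of_expression_terms(self, rng):
        data, weights, Y = random_instance(rng)
        scaled = ModelData(
            X_S=13.0 * data.X_S, X_R=13.0 * data.X_R, pairs=data.pairs,
            r=data.r, parent_index=data.parent_index,
        )
        assert total_objective(Y, scaled, weights).total == pytest.approx(
            total_objective(Y, data, weights).total, rel=1e-9
        )


class TestGradient:
    def test_matches_central_differences(self, rng):
        h = 1e-6
        for _ in range(10):
            data, weights, Y = random_instance(
                rng, n_pops=int(rng.integers(3, 10)),
                n_spots=int(rng.integers(8, 20)), n_genes=int(rng.integers(5, 15)),
            )
            g = gradient(Y, data, weights)
            for _ in range(5):
                c, i = rng.integers(Y.shape[0]), rng.integers(Y.shape[1])
                Yp, Ym = Y.copy(), Y.copy()
                Yp[c, i] += h
                Ym[c, i] -= h
                fd = (
                    total_objective(Yp, data, weights).total
                    - total_objective(Ym, data, weights).total
                ) / (2 * h)
                assert abs(fd - g[c, i]) / max(abs(fd), 1e-8) <= 1e-5

    def test_zero_directional_derivative_along_flat_direction(self, rng):
        """The population term is scale-invariant per row, so the derivative
        along a row-scaling direction vanishes."""
        data, _, Y = random_instance(rng)
        w = ObjectiveWeights(lambda_C=1.0, theta=0.0, nbar=4.0)
        # isolate the population term by subtracting the spot-term gradient
        g_full = gradient(Y, data, w)
        g_spot = gradient(Y, data, ObjectiveWeights(theta=0.0, nbar=4.0))
        g_pop = g_full - g_spot
        direction = np.zeros_like(Y)
        direction[2] = Y[2]  # scaling row 2
        assert abs((g_pop * direction).sum()) < 1e-8

    def test_linearity_of_weighted_gradient(self, rng):
        data, weights, Y = random_instance(rng)
        g = gradient(Y, data, weights)
        base = ObjectiveWeights(theta=weights.theta, nbar=weights.nbar)
        g_base = gradient(Y, data, base)
        parts = np.zeros_like(Y)
        for lam_name, lam in (
            ("lambda_C", weights.lambda_C),
            ("lambda_G", weights.lambda_G),
            ("lambda_S", weights.lambda_S),
            ("lambda_A", weights.lambda_A),
        ):
            solo = ObjectiveWeights(**{lam_name: 1.0}, theta=weights.theta, nbar=weights.nbar)
            parts += lam * (gradient(Y, data, solo) - g_base)
        np.testing.assert_allclose(g, g_base + parts, rtol=1e-9, atol=1e-12)
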