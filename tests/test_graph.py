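"""Kernel, diffusion-operator, and time-scale selection machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ephate.graph import (
    AffinityMatrix,
    DataMatrix,
    DiffusionOperator,
    Spectrum,
    adaptive_bandwidths,
    alpha_decay_kernel,
    entropy_curve,
    knee_point,
    operator_spectrum,
    pairwise_distances,
    power_operator,
    row_normalize,
    select_diffusion_time,
    symmetric_conjugate_eigenvalues,
    von_neumann_entropy,
)
from ephate.multiview import view_operator

LINE_POINTS = np.array([[0.0], [1.0], [3.0]])


class TestDataMatrix:
    def test_rejects_too_few_subjects(self):
        with pytest.raises(ValueError, match="at least 3"):
            DataMatrix(["a", "b"], np.zeros((2, 3)))

    def test_rejects_duplicate_ids_and_missing_values(self):
        with pytest.raises(ValueError, match="unique"):
            DataMatrix(["a", "a", "b"], np.zeros((3, 2)))
        bad = np.zeros((3, 2))
        bad[1, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            DataMatrix(["a", "b", "c"], bad)


class TestPairwiseDistances:
    def test_three_four_five_triangle(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0], [3.0, 0.0]])
        D = pairwise_distances(X)
        assert D[0, 1] == pytest.approx(5.0)
        assert D[0, 2] == pytest.approx(3.0)
        assert D[1, 2] == pytest.approx(4.0)

    def test_identical_rows_have_zero_distance(self):
        X = np.vstack([np.ones(4), np.ones(4), np.zeros(4)])
        assert pairwise_distances(X)[0, 1] == 0.0

    def test_matches_bruteforce_double_loop(self, rng):
        X = rng.standard_normal((10, 6))
        D = pairwise_distances(X)
        for i in range(10):
            for j in range(10):
                expect = np.sqrt(((X[i] - X[j]) ** 2).sum())
                assert abs(D[i, j] - expect) < 1e-12
        assert np.allclose(D, D.T) and np.all(np.diag(D) == 0) and D.min() >= 0

    def test_too_few_subjects_error(self):
        with pytest.raises(ValueError):
            pairwise_distances(np.zeros((2, 3)))


class TestAdaptiveBandwidths:
    def test_line_points_by_inspection(self):
        D = pairwise_distances(LINE_POINTS)
        assert np.allclose(adaptive_bandwidths(D, 1), [1.0, 1.0, 2.0])

    def test_k_equal_n_minus_one_gives_row_maximum(self, rng):
        D = pairwise_distances(rng.standard_normal((8, 3)))
        assert np.allclose(adaptive_bandwidths(D, 7), D.max(axis=1))

    def test_matches_sort_oracle(self, rng):
        D = pairwise_distances(rng.standard_normal((20, 4)))
        eps = adaptive_bandwidths(D, 5)
        for i in range(20):
            row = np.sort(D[i])
            assert eps[i] == row[5]

    def test_k_out_of_range_error(self):
        D = pairwise_distances(LINE_POINTS)
        with pytest.raises(ValueError):
            adaptive_bandwidths(D, 3)

    def test_duplicate_points_warn_and_stay_positive(self):
        X = np.array([[0.0], [0.0], [2.0], [5.0]])
        D = pairwise_distances(X)
        with pytest.warns(UserWarning, match="duplicate"):
            eps = adaptive_bandwidths(D, 1)
        assert np.all(eps > 0)


class TestAlphaDecayKernel:
    def test_zero_distance_gives_unit_affinity(self, rng):
        D = pairwise_distances(rng.standard_normal((5, 3)))
        K = alpha_decay_kernel(D, adaptive_bandwidths(D, 2), 40.0).values
        assert np.all(np.diag(K) == 1.0)

    def test_line_points_closed_form(self):
        D = pairwise_distances(LINE_POINTS)
        eps = adaptive_bandwidths(D, 1)
        K = alpha_decay_kernel(D, eps, 2.0).values
        assert K[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)
        expect_02 = 0.5 * np.exp(-9.0) + 0.5 * np.exp(-2.25)
        assert K[0, 2] == pytest.approx(expect_02, abs=1e-12)

    @settings(max_examples=25, derandomize=True)
    @given(scale=st.floats(min_value=0.1, max_value=50.0))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(1)
        D = pairwise_distances(rng.standard_normal((9, 4)))
        eps = adaptive_bandwidths(D, 3)
        K1 = alpha_decay_kernel(D, eps, 7.0).values
        K2 = alpha_decay_kernel(scale * D, scale * eps, 7.0).values
        assert np.allclose(K1, K2, rtol=1e-12, atol=1e-15)

    def test_symmetry_and_range_on_random_input(self, rng):
        D = pairwise_distances(rng.standard_normal((15, 5)))
        K = alpha_decay_kernel(D, adaptive_bandwidths(D, 4), 40.0).values
        assert np.allclose(K, K.T, atol=1e-12)
        assert K.min() >= 0 and K.max() <= 1

    def test_nonpositive_alpha_error(self):
        D = pairwise_distances(LINE_POINTS)
        with pytest.raises(ValueError):
            alpha_decay_kernel(D, adaptive_bandwidths(D, 1), 0.0)


class TestRowNormalize:
    def test_hand_example(self):
        P = row_normalize(np.array([[2.0, 2.0], [1.0, 3.0]])).values
        assert np.allclose(P, [[0.5, 0.5], [0.25, 0.75]])

    def test_identity_fixed_point(self):
        assert np.array_equal(row_normalize(np.eye(4)).values, np.eye(4))

    def test_rows_sum_to_one(self, random_operator):
        assert np.allclose(random_operator.values.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_row_error(self):
        with pytest.raises(ValueError, match="zero row"):
            row_normalize(np.array([[0.0, 0.0], [1.0, 1.0]]))


class TestSpectrum:
    def test_identity_operator_spectrum_is_all_ones(self):
        op = row_normalize(AffinityMatrix(np.eye(5), k=1, alpha=1.0))
        lam = symmetric_conjugate_eigenvalues(op).eigenvalues
        assert np.allclose(lam, 1.0)

    @pytest.mark.parametrize("a", [0.1, 0.5, 0.9])
    def test_two_by_two_closed_form(self, a):
        op = row_normalize(AffinityMatrix(np.array([[1.0, a], [a, 1.0]]), k=1, alpha=1.0))
        lam = symmetric_conjugate_eigenvalues(op).eigenvalues
        assert lam[0] == pytest.approx(1.0, abs=1e-12)
        assert lam[1] == pytest.approx((1 - a) / (1 + a), abs=1e-12)

    def test_conjugate_matches_direct_eigendecomposition(self, rng):
        op = view_operator(rng.standard_normal((10, 3)), k=3, alpha=5.0)
        lam = symmetric_conjugate_eigenvalues(op).eigenvalues
        direct = np.sort(np.real(np.linalg.eigvals(op.values)))[::-1]
        assert np.allclose(lam, direct, atol=1e-8)

    def test_missing_affinity_error(self):
        op = row_normalize(np.array([[0.5, 0.5], [0.3, 0.7]]))
        with pytest.raises(ValueError, match="symmetric affinity"):
            symmetric_conjugate_eigenvalues(op)

    def test_operator_spectrum_falls_back_for_products(self, random_operator):
        P2 = random_operator.values @ random_operator.values
        op = DiffusionOperator(P2)
        lam = operator_spectrum(op).eigenvalues
        assert lam[0] == pytest.approx(1.0, abs=1e-8)
        assert np.all(np.diff(lam) <= 1e-12)


class TestVonNeumannEntropy:
    def test_single_eigenvalue_zero_entropy(self):
        assert von_neumann_entropy(Spectrum(np.array([1.0])), 3) == 0.0

    def test_uniform_spectrum_log_n(self):
        spec = Spectrum(np.ones(4))
        for t in (1, 5, 50):
            assert von_neumann_entropy(spec, t) == pytest.approx(np.log(4))

    def test_direct_evaluation(self):
        spec = Spectrum(np.array([1.0, 0.5, 0.25]))
        lam = np.array([1.0, 0.5, 0.25])
        eta = lam / lam.sum()
        expect = -(eta * np.log(eta)).sum()
        assert von_neumann_entropy(spec, 1) == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(0.9557, abs=1e-4)

    def test_non_increasing_in_t_on_random_spectra(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            lam = np.sort(rng.uniform(0, 1, size=12))[::-1]
            lam[0] = 1.0
            H = entropy_curve(Spectrum(lam), 40)
            assert np.all(np.diff(H) <= 1e-12)

    def test_bounds(self, random_operator):
        spec = symmetric_conjugate_eigenvalues(random_operator)
        for t in (1, 10, 100):
            H = von_neumann_entropy(spec, t)
            assert 0.0 <= H <= np.log(spec.eigenvalues.size) + 1e-12


class TestDiffusionTimeSelection:
    def test_flat_curve_breaks_tie_to_smallest(self):
        # all eigenvalues equal -> H constant in t -> knee defaults to t=1
        assert select_diffusion_time(Spectrum(np.ones(5)), 20) == 1

    def test_piecewise_linear_bend(self):
        curve = np.concatenate([5.0 - 1.5 * np.arange(3), 2.0 - 0.01 * np.arange(8)])
        assert knee_point(curve) == 2  # bend at index 2 (t=3 in 1-based time)

    def test_affine_rescaling_invariance(self, rng):
        for _ in range(10):
            curve = np.sort(rng.uniform(0, 5, 30))[::-1]
            a, b = rng.uniform(0.1, 10), rng.uniform(-5, 5)
            assert knee_point(curve) == knee_point(a * curve + b)

    def test_selected_time_in_range(self, random_operator):
        spec = symmetric_conjugate_eigenvalues(random_operator)
        t = select_diffusion_time(spec, 150)
        assert 1 <= t <= 150


class TestPowerOperator:
    def test_identity_powers_to_identity(self):
        op = row_normalize(np.eye(6))
        assert np.array_equal(power_operator(op, 7).values, np.eye(6))

    def test_power_one_is_unchanged(self, random_operator):
        assert power_operator(random_operator, 1) is random_operator

    def test_hand_squared_example(self):
        op = row_normalize(np.array([[2.0, 2.0], [1.0, 3.0]]))
        P2 = power_operator(op, 2).values
        assert np.allclose(P2, [[0.375, 0.625], [0.3125, 0.6875]], atol=1e-12)

    def test_powers_stay_row_stochastic(self, random_operator):
        for t in (2, 5, 20):
            Pt = power_operator(random_operator, t).values
            assert np.allclose(Pt.sum(axis=1), 1.0, atol=1e-8)
            assert Pt.min() >= 0

    def test_invalid_time_error(self, random_operator):
        with pytest.raises(ValueError):
            power_operator(random_operator, 0)


def test_subject_permutation_equivariance_is_exact(rng):
    """Permuting subjects permutes the diffusion operator bitwise."""
    X = rng.standard_normal((14, 5))
    perm = rng.permutation(14)
    P = view_operator(X, k=4, alpha=40.0).values
    P_perm = view_operator(X[perm], k=4, alpha=40.0).values
    assert np.array_equal(P_perm, P[np.ix_(perm, perm)])
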