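import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from clusterhsic.kernels import (
    GAUSSIAN_EXPONENT_SCALE,
    bray_curtis_dissimilarity,
    bray_curtis_kernel,
    double_center,
    gaussian_kernel,
    median_heuristic,
    pairwise_sq_distances,
    psd_project,
)

from conftest import center

finite_rows = arrays(
    np.float64,
    st.tuples(st.integers(3, 8), st.integers(1, 4)),
    elements=st.floats(-50, 50, allow_nan=False),
)


class TestPairwiseSqDistances:
    def test_pythagorean_pair(self):
        D2 = pairwise_sq_distances([[0.0, 0.0], [3.0, 4.0]])
        assert np.allclose(D2, [[0.0, 25.0], [25.0, 0.0]])

    def test_identical_rows_give_zero_matrix(self):
        D2 = pairwise_sq_distances(np.ones((4, 3)))
        assert np.allclose(D2, 0.0)

    def test_matches_brute_force_double_loop(self, rng):
        X = rng.normal(size=(3, 5))
        D2 = pairwise_sq_distances(X)
        for i in range(3):
            for j in range(3):
                assert D2[i, j] == pytest.approx(np.sum((X[i] - X[j]) ** 2))

    def test_nonfinite_input_names_row(self):
        X = np.ones((3, 2))
        X[1, 0] = np.nan
        with pytest.raises(ValueError, match=r"row\(s\) \[1\]"):
            pairwise_sq_distances(X)


class TestMedianHeuristic:
    def test_single_pair(self):
        assert median_heuristic([[0.0], [5.0]]) == pytest.approx(5.0)

    def test_odd_pair_count_median(self):
        # collinear points at 0, 1, 2: pair distances {1, 1, 2}
        assert median_heuristic([[0.0], [1.0], [2.0]]) == pytest.approx(1.0)

    def test_matches_sorted_pair_list(self, rng):
        X = rng.normal(size=(20, 3))
        dists = sorted(
            np.linalg.norm(X[i] - X[j]) for i in range(20) for j in range(i + 1, 20)
        )
        assert median_heuristic(X) == pytest.approx(np.median(dists))

    def test_identical_rows_ask_for_explicit_bandwidth(self):
        with pytest.raises(ValueError, match="bandwidth"):
            median_heuristic(np.ones((5, 2)))


class TestGaussianKernel:
    def test_identical_rows_all_ones(self):
        K = gaussian_kernel(np.ones((4, 2)), bandwidth=1.0)
        assert np.allclose(K, 1.0)

    def test_closed_form_entry(self):
        # two points at distance h * sqrt(scale) give exp(-1)
        h = 2.0
        d = h * np.sqrt(GAUSSIAN_EXPONENT_SCALE)
        K = gaussian_kernel([[0.0], [d]], bandwidth=h)
        assert K[0, 1] == pytest.approx(np.exp(-1.0))

    def test_composes_with_distance_and_median_oracles(self, rng):
        X = rng.normal(size=(5, 3))
        h = median_heuristic(X)
        K = gaussian_kernel(X)
        expected = np.exp(-pairwise_sq_distances(X) / (GAUSSIAN_EXPONENT_SCALE * h**2))
        assert np.allclose(K, expected)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError, match="bandwidth"):
            gaussian_kernel(np.eye(3), bandwidth=0.0)

    @given(finite_rows)
    def test_entries_in_unit_interval_with_unit_diagonal(self, X):
        try:
            K = gaussian_kernel(X)
        except ValueError:
            return  # degenerate draw: all rows identical
        assert np.all(K > 0.0) and np.all(K <= 1.0)
        assert np.allclose(np.diag(K), 1.0)

    def test_invariant_under_row_permutation(self, rng):
        X = rng.normal(size=(7, 3))
        pi = rng.permutation(7)
        K = gaussian_kernel(X, bandwidth=1.3)
        assert np.allclose(K[np.ix_(pi, pi)], gaussian_kernel(X[pi], bandwidth=1.3))


class TestBrayCurtis:
    def test_identical_rows_give_zero_kernel(self):
        X = np.tile([1.0, 2.0, 3.0], (4, 1))
        assert np.allclose(bray_curtis_dissimilarity(X), 0.0)
        assert np.allclose(bray_curtis_kernel(X), 0.0)

    def test_disjoint_support_is_maximally_dissimilar(self):
        D = bray_curtis_dissimilarity([[1.0, 0.0], [0.0, 3.0]])
        assert D[0, 1] == pytest.approx(1.0)

    def test_matches_literal_feature_loop(self, rng):
        X = rng.uniform(0.0, 1.0, size=(6, 4)) + 0.01
        D = bray_curtis_dissimilarity(X)
        for i in range(6):
            for j in range(6):
                num = sum(abs(X[i, k] - X[j, k]) for k in range(4))
                den = sum(X[i, k] + X[j, k] for k in range(4))
                assert D[i, j] == pytest.approx(num / den)

    def test_dissimilarities_in_unit_interval_zero_diag(self, rng):
        X = rng.uniform(0.0, 5.0, size=(8, 6)) + 1e-3
        D = bray_curtis_dissimilarity(X)
        assert np.all(D >= 0.0) and np.all(D <= 1.0)
        assert np.allclose(np.diag(D), 0.0)

    def test_kernel_is_psd(self, rng):
        X = rng.uniform(0.0, 1.0, size=(10, 5)) + 0.01
        K = bray_curtis_kernel(X)
        w = np.linalg.eigvalsh(K)
        assert w.min() >= -1e-8 * max(w.max(), 1.0)

    def test_negative_entry_identifies_sample(self):
        X = np.ones((3, 2))
        X[2, 1] = -0.5
        with pytest.raises(ValueError, match=r"\[2\]"):
            bray_curtis_dissimilarity(X)

    def test_zero_row_sum_identifies_sample(self):
        X = np.ones((3, 2))
        X[0] = 0.0
        with pytest.raises(ValueError, match=r"\[0\]"):
            bray_curtis_dissimilarity(X)


class TestDoubleCenter:
    def test_constant_matrix_maps_to_zero(self):
        assert np.allclose(double_center(np.full((5, 5), 3.7)), 0.0)

    def test_idempotent(self, rng):
        K = rng.normal(size=(6, 6))
        K = (K + K.T) / 2
        once = double_center(K)
        assert np.allclose(double_center(once), once)

    def test_closed_form(self, rng):
        K = rng.normal(size=(5, 5))
        K = (K + K.T) / 2
        assert np.allclose(double_center(K), center(K))

    def test_row_and_column_sums_vanish(self, rng):
        K = rng.normal(size=(7, 7))
        C = double_center((K + K.T) / 2)
        assert np.allclose(C.sum(axis=0), 0.0, atol=1e-10)
        assert np.allclose(C.sum(axis=1), 0.0, atol=1e-10)


class TestPsdProject:
    def test_identity_unchanged(self):
        assert np.allclose(psd_project(np.eye(4)), np.eye(4))

    def test_clamps_negative_eigenvalue(self):
        K = psd_project(np.diag([1.0, -1.0]))
        assert np.allclose(np.linalg.eigvalsh(K), [0.0, 1.0])

    def test_output_is_psd_and_projection_idempotent(self, rng):
        K = rng.normal(size=(8, 8))
        K = (K + K.T) / 2
        P = psd_project(K)
        w = np.linalg.eigvalsh(P)
        assert w.min() >= -1e-8 * max(abs(w).max(), 1.0)
        assert np.allclose(psd_project(P), P, atol=1e-10)
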