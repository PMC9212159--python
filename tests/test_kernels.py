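"""Kernel primitives, double-centering, and the K_c coefficient itself."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from kercor import (KernelSpec, TimeSeriesPair, double_center, kernelize,
                    kernelized_correlation, pair_kernel_matrix,
                    polynomial_kernel, rbf_kernel, standardize)

# strategy for well-behaved (finite, non-constant) series of length 5-12
series = hnp.arrays(
    float, st.shared(st.integers(5, 12), key="T"),
    elements=st.floats(-5, 5, allow_nan=False, width=32),
).filter(lambda v: v.std() > 0.05)


class TestStandardize:
    def test_simple(self):
        np.testing.assert_allclose(standardize([1, 2, 3]), [-1, 0, 1])

    def test_constant_raises(self):
        with pytest.raises(ValueError, match="constant"):
            standardize([5, 5, 5])

    def test_sinusoid_zero_mean_unit_sd(self):
        t = np.arange(0, 120, 7.0)
        z = standardize(2 * np.sin(t * np.pi / 42) - 0.5)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1) < 1e-12


class TestKernelFunctions:
    @pytest.mark.parametrize(
        "u, v, d, expected",
        [((0, 0), (3, -7), 2, 1.0),    # zero inner product
         ((1, 1), (1, 1), 2, 9.0),     # (1+2)^2
         ((1, -1), (-1, 1), 3, -1.0)], # (1-2)^3
    )
    def test_polynomial(self, u, v, d, expected):
        assert polynomial_kernel(u, v, d) == pytest.approx(expected)

    def test_polynomial_degree_check(self):
        with pytest.raises(ValueError):
            polynomial_kernel((1, 1), (1, 1), 1)

    def test_rbf_identity_point(self):
        assert rbf_kernel((2.3, -1), (2.3, -1), gamma=3.7) == 1.0

    def test_rbf_hand_value(self):
        # ||u-v||^2 = 2, gamma = 0.5 -> exp(-1)
        assert rbf_kernel((0, 0), (1, 1), 0.5) == pytest.approx(np.exp(-1))

    def test_rbf_far_points_underflow_to_zero(self):
        assert rbf_kernel((0, 0), (0, 1e6), 0.5) == 0.0

    def test_rbf_gamma_check(self):
        with pytest.raises(ValueError):
            rbf_kernel((0, 0), (1, 1), gamma=0.0)


class TestGramMatrix:
    def test_constant_series_all_ones(self):
        pair = TimeSeriesPair([1, 1, 1], [2, 2, 2])
        kp = pair_kernel_matrix(pair, KernelSpec(standardize=False))
        np.testing.assert_allclose(kp.K, np.ones((3, 3)))

    def test_rbf_unit_diagonal_and_symmetry(self, rng):
        pair = TimeSeriesPair(rng.normal(size=8), rng.normal(size=8))
        kp = pair_kernel_matrix(pair, KernelSpec(gamma=1.3))
        np.testing.assert_allclose(np.diag(kp.K), 1.0)
        np.testing.assert_array_equal(kp.K, kp.K.T)

    def test_rbf_gram_psd(self, rng):
        pair = TimeSeriesPair(rng.normal(size=10), rng.normal(size=10))
        kp = pair_kernel_matrix(pair, KernelSpec(gamma=0.5))
        eig = np.linalg.eigvalsh(kp.K)
        assert eig.min() > -1e-10


class TestDoubleCenter:
    # the 3x3 kernel matrix and its centered form from the worked example;
    # printed values are rounded, so match at the third decimal
    K_PRINTED = np.array([[1, 0, 0], [0, 1, 0.988], [0, 0.988, 1.0]])
    KC_PRINTED = np.array([
        [0.886, -0.443, -0.443],
        [-0.443, 0.227, 0.216],
        [-0.443, 0.216, 0.227],
    ])

    def test_worked_example(self):
        Kc = double_center(self.K_PRINTED)
        assert np.abs(Kc - self.KC_PRINTED).max() < 1e-3
        # the top-left entry matches the printed rounding exactly
        assert round(Kc[0, 0], 3) == 0.886

    def test_all_ones_annihilated(self):
        np.testing.assert_allclose(double_center(np.ones((4, 4))), 0.0,
                                   atol=1e-15)

    def test_row_and_column_sums_zero(self, rng):
        A = rng.normal(size=(6, 6))
        Kc = double_center((A + A.T) / 2)
        np.testing.assert_allclose(Kc.sum(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(Kc.sum(axis=1), 0.0, atol=1e-12)

    def test_matches_projection_matrix_oracle(self, rng):
        # independent formula: H K H with explicit H = I - 11'/T
        A = rng.normal(size=(5, 5))
        K = (A + A.T) / 2
        H = np.eye(5) - np.ones((5, 5)) / 5
        np.testing.assert_allclose(double_center(K), H @ K @ H, atol=1e-12)

    def test_non_square_raises(self):
        with pytest.raises(ValueError):
            double_center(np.ones((3, 4)))


class TestKernelize:
    def test_kernelized_vectors_sum_to_zero(self, rng, rbf_std):
        pair = TimeSeriesPair(rng.normal(size=9), rng.normal(size=9))
        kp = kernelize(pair, rbf_std)
        assert abs(kp.xk.sum()) < 1e-10
        assert abs(kp.yk.sum()) < 1e-10

    def test_identical_series_identical_vectors(self, rng, rbf_raw):
        x = rng.normal(size=7)
        kp = kernelize(TimeSeriesPair(x, x.copy()), rbf_raw)
        np.testing.assert_array_equal(kp.xk, kp.yk)

    def test_centered_matrix_kills_constants(self, rng, rbf_raw):
        pair = TimeSeriesPair(rng.normal(size=8), rng.normal(size=8))
        kp = kernelize(pair, rbf_raw)
        np.testing.assert_allclose(kp.Kc @ np.ones(8), 0.0, atol=1e-10)


class TestKernelizedCorrelation:
    def test_affine_pair_is_one(self):
        x = np.array([0.3, 1.7, -2.2, 0.9, 1.1])
        pair = TimeSeriesPair(x, 2 * x + 3)
        assert kernelized_correlation(pair, KernelSpec(gamma=0.5)) == pytest.approx(1.0)

    def test_negated_pair_is_minus_one(self, rng):
        x = rng.normal(size=8)
        pair = TimeSeriesPair(x, -x)
        for gamma in (0.1, 0.5, 3.0):
            spec = KernelSpec(gamma=gamma, standardize=False)
            assert kernelized_correlation(pair, spec) == pytest.approx(-1.0)

    @settings(derandomize=True, max_examples=40)
    @given(x=series, y=series)
    def test_bounded_and_symmetric(self, x, y):
        spec = KernelSpec(gamma=0.5, standardize=False)
        try:
            v1 = kernelized_correlation(TimeSeriesPair(x, y), spec)
            v2 = kernelized_correlation(TimeSeriesPair(y, x), spec)
        except ValueError:
            return  # degenerate kernelization is a legitimate refusal
        assert -1.0 <= v1 <= 1.0
        assert v1 == pytest.approx(v2, abs=1e-9)

    @settings(derandomize=True, max_examples=25)
    @given(x=series, y=series, b=st.floats(-10, 10))
    def test_rbf_sign_antisymmetry_and_location_invariance(self, x, y, b):
        spec = KernelSpec(gamma=0.5, standardize=False)
        try:
            v = kernelized_correlation(TimeSeriesPair(x, y), spec)
            v_neg = kernelized_correlation(TimeSeriesPair(x, -y), spec)
            v_shift = kernelized_correlation(
                TimeSeriesPair(x, x + b * np.ones_like(x)), spec)
        except ValueError:
            return
        assert v_neg == pytest.approx(-v, abs=1e-9)
        assert v_shift == pytest.approx(1.0, abs=1e-9)

    def test_large_gamma_limit_is_pearson(self, rng):
        from kercor import pearson
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        spec = KernelSpec(gamma=1e6, standardize=False)
        kc = kernelized_correlation(TimeSeriesPair(x, y), spec)
        assert kc == pytest.approx(pearson(x, y), abs=1e-6)

    def test_degenerate_kernelization_raises(self):
        # tiny gamma collapses the Gram matrix towards all-ones
        pair = TimeSeriesPair([0.0, 1e-9, 2e-9], [0.0, 1e-9, 2e-9])
        with pytest.raises(ValueError, match="degenerate"):
            kernelized_correlation(pair, KernelSpec(gamma=1e-12,
                                                    standardize=False))

    def test_standardization_mode_changes_value(self, noiseless_case1):
        raw = kernelized_correlation(noiseless_case1,
                                     KernelSpec(gamma=0.5, standardize=False))
        std = kernelized_correlation(noiseless_case1,
                                     KernelSpec(gamma=0.5, standardize=True))
        assert raw != pytest.approx(std, abs=1e-4)


class TestKernelSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        {"family": "rbf", "gamma": -1.0},
        {"family": "rbf", "degree": 2},
        {"family": "polynomial", "degree": 1},
        {"family": "polynomial", "gamma": 0.5},
        {"family": "sigmoid"},
    ])
    def test_invalid_specs(self, kwargs):
        with pytest.raises(ValueError):
            KernelSpec(**kwargs)

    def test_defaults(self):
        spec = KernelSpec()
        assert spec.family == "rbf" and spec.gamma == 0.5 and spec.standardize
        assert KernelSpec(family="polynomial").degree == 2


class TestTimeSeriesPairValidation:
    @pytest.mark.parametrize("x, y", [
        ([1, 2], [1, 2]),                 # too short
        ([1, 2, np.nan], [1, 2, 3]),      # non-finite
        ([1, 2, 3], [1, 2, 3, 4]),        # length mismatch
    ])
    def test_invalid_pairs(self, x, y):
        with pytest.raises(ValueError):
            TimeSeriesPair(x, y)
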