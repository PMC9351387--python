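"""Working correlation matrices, derivatives, bounds and moment estimators."""

import numpy as np
import pytest
from scipy.linalg import cho_factor

from countraj import (
    CorrelationSpec,
    corr_derivative,
    corr_matrix,
    moment_rho,
    pearson_phi0,
    rho_bounds,
)

IND = CorrelationSpec("ind")
EXCH = CorrelationSpec("exch")
AR1 = CorrelationSpec("ar1")
AR1_NS = CorrelationSpec("ar1", spatial=False)


class TestCorrMatrix:
    def test_ind_identity(self):
        np.testing.assert_array_equal(corr_matrix(IND, 0.0, np.arange(1, 6)), np.eye(5))

    def test_spatial_ar1_large_gap_decay(self):
        t = np.arange(1.0, 31.0)
        R = corr_matrix(AR1, 0.75, t)
        assert R[0, 29] == pytest.approx(0.75**29)
        assert round(float(R[0, 29]), 4) == 0.0002

    def test_exch_closed_form_determinant(self):
        R = corr_matrix(EXCH, 0.5, np.arange(1.0, 4.0))
        np.testing.assert_allclose(R - np.diag(np.diag(R)), 0.5 * (np.ones((3, 3)) - np.eye(3)))
        assert np.linalg.det(R) == pytest.approx((1 + 2 * 0.5) * (1 - 0.5) ** 2)

    def test_out_of_bounds_rho_rejected(self):
        with pytest.raises(ValueError):
            corr_matrix(EXCH, -0.9, np.arange(1.0, 6.0))
        with pytest.raises(ValueError):
            corr_matrix(AR1, 1.5, np.arange(1.0, 6.0))

    def test_negative_rho_fractional_gap_rejected(self):
        with pytest.raises(ValueError):
            corr_matrix(AR1, -0.5, np.array([1.0, 2.5]))

    def test_negative_rho_integer_gaps(self):
        R = corr_matrix(AR1, -0.5, np.array([1.0, 2.0, 4.0]))
        assert R[0, 1] == pytest.approx(-0.5)
        assert R[0, 2] == pytest.approx((-0.5) ** 3)
        assert R[1, 2] == pytest.approx(0.25)

    @pytest.mark.parametrize("n", [2, 4, 8])
    @pytest.mark.parametrize("rho", [-0.1, 0.0, 0.3, 0.8])
    def test_exch_determinant_identity_grid(self, n, rho):
        lo, _ = rho_bounds(EXCH, n)
        if rho <= lo:
            pytest.skip("rho below EXCH validity for this n")
        R = corr_matrix(EXCH, rho, np.arange(1.0, n + 1.0))
        np.testing.assert_allclose(
            np.linalg.det(R), (1 + (n - 1) * rho) * (1 - rho) ** (n - 1), rtol=1e-10
        )

    @pytest.mark.parametrize("n", [2, 5, 8])
    @pytest.mark.parametrize("rho", [-0.6, 0.2, 0.9])
    def test_equally_spaced_ar1_determinant_and_tridiagonal_inverse(self, n, rho):
        R = corr_matrix(AR1, rho, np.arange(1.0, n + 1.0))
        np.testing.assert_allclose(np.linalg.det(R), (1 - rho**2) ** (n - 1), rtol=1e-10)
        Rinv = np.linalg.inv(R)
        off_tri = Rinv.copy()
        for k in (-1, 0, 1):
            off_tri -= np.diag(np.diag(Rinv, k), k)
        np.testing.assert_allclose(off_tri, 0.0, atol=1e-10)

    def test_spatial_ar1_positive_definite_on_random_gaps(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            times = np.sort(rng.choice(np.arange(1, 60), size=12, replace=False)).astype(float)
            rho = rng.uniform(-0.95, 0.95)
            R = corr_matrix(AR1, rho, times)
            cho_factor(R)  # raises if not PD


class TestCorrDerivative:
    def test_trivial_zero_cases(self):
        t = np.arange(1.0, 5.0)
        np.testing.assert_array_equal(corr_derivative(IND, 0.0, t, 1), np.zeros((4, 4)))
        np.testing.assert_array_equal(corr_derivative(EXCH, 0.3, t, 2), np.zeros((4, 4)))
        D1 = corr_derivative(EXCH, 0.3, t, 1)
        np.testing.assert_array_equal(D1, np.ones((4, 4)) - np.eye(4))

    def test_ar1_entry_value(self):
        D = corr_derivative(AR1, 0.5, np.array([1.0, 3.0]), 1)
        assert D[0, 1] == pytest.approx(2 * 0.5)  # |dt| rho^{|dt|-1}
        assert D[0, 0] == 0.0

    def test_order_validation(self):
        with pytest.raises(ValueError):
            corr_derivative(AR1, 0.5, np.arange(1.0, 4.0), order=3)

    @pytest.mark.parametrize("spec", [EXCH, AR1, AR1_NS])
    def test_matches_finite_differences(self, spec):
        rng = np.random.default_rng(5)
        times = np.array([1.0, 2.0, 4.0, 7.0, 8.0, 12.0])
        for _ in range(10):
            rho = rng.uniform(0.05, 0.9)
            eps = 1e-6
            fd1 = (corr_matrix(spec, rho + eps, times) - corr_matrix(spec, rho - eps, times)) / (2 * eps)
            np.testing.assert_allclose(
                corr_derivative(spec, rho, times, 1), fd1, rtol=1e-6, atol=1e-7
            )
            fd2 = (
                corr_derivative(spec, rho + eps, times, 1)
                - corr_derivative(spec, rho - eps, times, 1)
            ) / (2 * eps)
            np.testing.assert_allclose(
                corr_derivative(spec, rho, times, 2), fd2, rtol=1e-5, atol=1e-6
            )


class TestRhoBounds:
    def test_exch_bounds(self):
        lo, hi = rho_bounds(EXCH, 2)
        assert lo == pytest.approx(-1.0, abs=1e-5)
        lo, _ = rho_bounds(EXCH, 11)
        assert lo == pytest.approx(-0.1, abs=1e-5)

    @pytest.mark.parametrize("spec", [EXCH, AR1])
    @pytest.mark.parametrize("n", [2, 5, 20])
    def test_midpoint_is_positive_definite(self, spec, n):
        lo, hi = rho_bounds(spec, n)
        R = corr_matrix(spec, (lo + hi) / 2, np.arange(1.0, n + 1.0))
        cho_factor(R)


class TestMomentEstimators:
    def test_zero_residuals_give_zero_rho(self):
        stde = np.zeros(6)
        assert moment_rho(stde, np.arange(1.0, 7.0), EXCH, 1) == 0.0
        assert moment_rho(stde, np.arange(1.0, 7.0), AR1, 1) == 0.0

    def test_nonspatial_unit_products(self):
        # (1*1 + 1*1) / (3 - 1 - 0) = 1.0 before clipping to the open interval
        with pytest.warns(UserWarning):
            est = moment_rho(np.ones(3), np.arange(1.0, 4.0), AR1_NS, 0)
        assert est == pytest.approx(1.0, abs=1e-5)

    def test_spatial_signed_root_matches_brute_force(self):
        rng = np.random.default_rng(8)
        times = np.array([1.0, 2.0, 5.0, 6.0, 9.0, 10.0, 14.0])
        stde = 0.6 * rng.normal(size=7)
        j = 1
        total = 0.0
        for i in range(6):
            p = stde[i] * stde[i + 1]
            gap = times[i + 1] - times[i]
            total += np.sign(p) * np.abs(p) ** (1.0 / gap)
        expected = total / (7 - 1 - j)
        assert moment_rho(stde, times, AR1, j) == pytest.approx(expected)

    def test_exch_pairwise_sum_matches_loop(self):
        rng = np.random.default_rng(9)
        stde = rng.normal(size=6)
        j = 2
        total = sum(
            stde[i] * stde[ip] for i in range(5) for ip in range(i + 1, 6)
        )
        expected = total / (6 * 5 / 2 - j)
        assert moment_rho(stde, np.arange(1.0, 7.0), EXCH, j) == pytest.approx(expected)

    def test_denominator_guard(self):
        with pytest.raises(ValueError):
            moment_rho(np.ones(3), np.arange(1.0, 4.0), AR1_NS, 2)

    def test_pearson_phi0(self):
        assert pearson_phi0(np.full(5, 2.0), 1) == pytest.approx(5 * 4.0 / 4)
        assert pearson_phi0(np.zeros(4), 1) == 0.0
        pe = np.array([0.5, -1.2, 2.0, 0.1])
        assert pearson_phi0(pe, 2) == pytest.approx(np.sum(pe**2) / 2)
        with pytest.raises(ValueError):
            pearson_phi0(np.ones(2), 2)
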