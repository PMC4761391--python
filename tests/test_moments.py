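"""Raw/central moment oracles, Hahn polynomials, basis orthonormality and
transform round trips."""

import math

import mpmath
import numpy as np
import pytest

from memopred.moments import (
    MomentError,
    build_hahn_basis,
    central_moments,
    centroid,
    hahn_moments,
    hahn_polynomial,
    hahn_transform,
    hahn_weight,
    moment_orders,
    pochhammer,
    raw_moments,
    reconstruct_from_hahn,
    write_moments_tsv,
)
from memopred.synthetic_data import (
    brute_force_central_moment,
    brute_force_raw_moment,
    fixture_matrices,
)


class TestOrderEnumeration:
    def test_triangle_order3_is_10_lexicographic(self):
        orders = moment_orders(3)
        assert len(orders) == 10
        assert orders[:4] == [(0, 0), (0, 1), (0, 2), (0, 3)]
        assert orders == sorted(orders)

    def test_grid_order3_is_16(self):
        assert len(moment_orders(3, "grid")) == 16


class TestRawCentralMoments:
    def test_all_ones_2x2(self):
        ms = raw_moments(np.ones((2, 2)), 1)
        assert ms.get(0, 0) == 4 and ms.get(1, 0) == 2 and ms.get(0, 1) == 2

    def test_m00_is_total_mass(self, rng):
        M = rng.random((5, 7))
        assert raw_moments(M, 0).get(0, 0) == pytest.approx(M.sum())

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 17))
            M = rng.integers(0, 21, (n, n)).astype(float)
            ms = raw_moments(M, 3)
            for x, y, v in ms.entries:
                assert v == pytest.approx(brute_force_raw_moment(M, x, y), rel=1e-12)

    def test_centroid_examples(self):
        assert centroid(np.ones((2, 2))) == (0.5, 0.5)
        M = np.zeros((5, 5))
        M[2, 3] = 7.0
        assert centroid(M) == (2.0, 3.0)

    def test_centroid_matches_oracle(self, rng):
        M = rng.random((3, 3)) + 0.1
        p, q = centroid(M)
        m00 = brute_force_raw_moment(M, 0, 0)
        assert p == pytest.approx(brute_force_raw_moment(M, 1, 0) / m00)
        assert q == pytest.approx(brute_force_raw_moment(M, 0, 1) / m00)

    def test_centroid_undefined_for_zero_mass(self):
        with pytest.raises(MomentError):
            centroid(np.zeros((3, 3)))

    def test_central_first_order_vanishes_and_mass_preserved(self, rng):
        M = rng.random((6, 4)) + 0.01
        ms = central_moments(M, 3)
        assert abs(ms.get(1, 0)) <= 1e-9 * max(1.0, abs(ms.get(0, 0)))
        assert abs(ms.get(0, 1)) <= 1e-9 * max(1.0, abs(ms.get(0, 0)))
        assert ms.get(0, 0) == pytest.approx(M.sum())

    def test_central_matches_oracle(self, rng):
        M = rng.integers(0, 9, (5, 5)).astype(float) + 1
        ms = central_moments(M, 3)
        for x, y, v in ms.entries:
            assert v == pytest.approx(brute_force_central_moment(M, x, y), abs=1e-9)

    def test_central_translation_invariance(self, rng):
        M = rng.integers(1, 21, (4, 4)).astype(float)
        big = np.zeros((10, 10))
        big[3:7, 2:6] = M
        a = central_moments(M, 3).values
        b = central_moments(big, 3).values
        np.testing.assert_allclose(a, b, rtol=1e-10, atol=1e-9)

    def test_empty_matrix_errors(self):
        with pytest.raises(MomentError):
            raw_moments(np.empty((0, 0)), 2)


class TestPochhammer:
    def test_examples(self):
        assert pochhammer(2, 3) == pytest.approx(24.0)
        assert pochhammer(-7.3, 0) == 1.0
        assert pochhammer(-3, 5) == 0.0

    def test_log_gamma_path_matches_product(self):
        direct = 0.5 * 1.5 * 2.5 * 3.5
        assert pochhammer(0.5, 4) == pytest.approx(direct, rel=1e-12)


def hahn_mpmath(n, r, N, mu, nu):
    """Independent arbitrary-precision evaluation of the Hahn polynomial."""
    with mpmath.workdps(50):
        pre = mpmath.rf(N + nu - 1, n) * mpmath.rf(N - 1, n)
        s = mpmath.mpf(0)
        for k in range(n + 1):
            s += (
                mpmath.rf(-n, k)
                * mpmath.rf(n + mu + nu + 1, k)
                * mpmath.rf(-r, k)
                / (mpmath.rf(nu + 1, k) * mpmath.rf(1 - N, k) * mpmath.factorial(k))
            )
        return float((-1) ** n * pre * s)


class TestHahnPolynomial:
    @pytest.mark.parametrize("mu,nu", [(0.0, 0.0), (0.5, 1.2)])
    def test_order_zero_is_one(self, mu, nu):
        for r in range(6):
            assert hahn_polynomial(0, r, 6, mu, nu) == pytest.approx(1.0)

    @pytest.mark.parametrize("mu,nu", [(0.0, 0.0), (0.5, 1.2), (2.0, 0.3)])
    def test_matches_high_precision_oracle(self, mu, nu):
        N = 8
        for n in range(4):
            for r in range(N):
                expected = hahn_mpmath(n, r, N, mu, nu)
                got = hahn_polynomial(n, r, N, mu, nu)
                assert got == pytest.approx(expected, rel=1e-10, abs=1e-10)

    def test_discrete_orthogonality_weighted_sum(self):
        N, mu, nu = 8, 0.7, 0.2
        w = [hahn_weight(r, N, mu, nu) for r in range(N)]
        H = [[hahn_polynomial(n, r, N, mu, nu) for r in range(N)] for n in range(4)]
        norms = [math.sqrt(sum(H[n][r] ** 2 * w[r] for r in range(N))) for n in range(4)]
        for m in range(4):
            for n in range(4):
                if m == n:
                    continue
                s = sum(H[m][r] * H[n][r] * w[r] for r in range(N))
                assert abs(s) / (norms[m] * norms[n]) < 1e-8

    def test_out_of_range_errors(self):
        with pytest.raises(MomentError):
            hahn_polynomial(4, 0, 4)
        with pytest.raises(MomentError):
            hahn_polynomial(1, 9, 4)


class TestHahnBasis:
    @pytest.mark.parametrize("N", [2, 4, 8, 16, 32, 64])
    def test_orthonormality_across_sizes(self, N):
        order = min(3, N - 1)
        basis = build_hahn_basis(N, order)
        gram = basis.table @ basis.table.T
        assert np.max(np.abs(gram - np.eye(order + 1))) < 1e-8

    def test_two_point_closed_form(self):
        basis = build_hahn_basis(2, 1)
        # orthonormal 2x2: constant row and antisymmetric row, both 1/sqrt(2)
        np.testing.assert_allclose(np.abs(basis.table), np.full((2, 2), 1 / math.sqrt(2)))

    def test_order_max_equal_N_rejected(self):
        with pytest.raises(MomentError):
            build_hahn_basis(4, 4)

    def test_table_consistent_with_polynomial_normalization(self):
        N, mu, nu = 7, 0.4, 1.1
        basis = build_hahn_basis(N, 3, mu, nu)
        for n in range(4):
            for r in range(N):
                expected = hahn_polynomial(n, r, N, mu, nu) * math.sqrt(
                    hahn_weight(r, N, mu, nu) / basis.d2[n]
                )
                assert basis.table[n, r] == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_chebyshev_recurrence_limit_agreement(self):
        # mu = nu = 0 reduces to discrete Chebyshev (independent recurrence)
        for N in (5, 16):
            x = np.arange(N, dtype=float)
            T = np.zeros((4, N))
            T[0] = 1.0
            T[1] = 2 * x - N + 1
            for n in range(1, 3):
                T[n + 1] = (
                    (2 * n + 1) * (2 * x - N + 1) * T[n] - n * (N * N - n * n) * T[n - 1]
                ) / (n + 1)
            T /= np.linalg.norm(T, axis=1, keepdims=True)
            basis = build_hahn_basis(N, 3)
            np.testing.assert_allclose(basis.table, T, atol=1e-7)


class TestHahnTransform:
    def test_zero_matrix_maps_to_zero(self):
        basis = build_hahn_basis(6, 3)
        assert np.all(hahn_moments(np.zeros((6, 6)), basis).values == 0)

    def test_basis_outer_product_gives_unit_entry(self):
        basis = build_hahn_basis(6, 3)
        # beta_pq = h~_1(q) h~_0(p)  ->  H[1, 0] = 1, all else 0
        M = np.outer(basis.table[0], basis.table[1])
        H = hahn_transform(M, basis)
        expected = np.zeros((4, 4))
        expected[1, 0] = 1.0
        np.testing.assert_allclose(H, expected, atol=1e-8)

    @pytest.mark.parametrize("N", [2, 5, 8, 12])
    def test_full_order_roundtrip(self, N, rng):
        basis = build_hahn_basis(N, N - 1)
        M = rng.integers(0, 21, (N, N)).astype(float)
        H = hahn_transform(M, basis)
        R = reconstruct_from_hahn(H, basis)
        assert np.max(np.abs(R - M)) < 1e-6

    def test_identity_roundtrip(self):
        basis = build_hahn_basis(5, 4)
        R = reconstruct_from_hahn(hahn_transform(np.eye(5), basis), basis)
        np.testing.assert_allclose(R, np.eye(5), atol=1e-8)

    def test_zero_grid_reconstructs_zero(self):
        basis = build_hahn_basis(4, 3)
        assert np.all(reconstruct_from_hahn(np.zeros((4, 4)), basis) == 0)

    def test_linearity(self, rng):
        basis = build_hahn_basis(7, 3)
        M1 = rng.random((7, 7))
        M2 = rng.random((7, 7))
        lhs = hahn_transform(2.5 * M1 - 1.25 * M2, basis)
        rhs = 2.5 * hahn_transform(M1, basis) - 1.25 * hahn_transform(M2, basis)
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)

    def test_dimension_mismatch(self):
        basis = build_hahn_basis(6, 3)
        with pytest.raises(MomentError):
            hahn_transform(np.ones((5, 5)), basis)
        with pytest.raises(MomentError):
            reconstruct_from_hahn(np.ones((3, 3)), basis)


class TestFixturesAndSerialization:
    def test_fixture_expected_values_match_vectorized(self):
        for fx in fixture_matrices(seed=5):
            M = fx["matrix"]
            ms = raw_moments(M, 3)
            for (x, y), v in fx["expected_raw"].items():
                assert ms.get(x, y) == pytest.approx(v, rel=1e-12, abs=1e-9)
            if "expected_centroid" in fx:
                assert centroid(M) == pytest.approx(fx["expected_centroid"])
                cs = central_moments(M, 3)
                for (x, y), v in fx["expected_central"].items():
                    assert cs.get(x, y) == pytest.approx(v, abs=1e-8)

    def test_tsv_serialization(self, tmp_path, rng):
        import pandas as pd

        sets = [raw_moments(rng.random((4, 4)), 2), central_moments(rng.random((4, 4)) + 0.1, 2)]
        path = tmp_path / "moments.tsv"
        write_moments_tsv(path, sets)
        frame = pd.read_csv(path, sep="\t")
        assert list(frame.columns) == ["family", "x", "y", "value"]
        assert len(frame) == 12
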