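import numpy as np
import pytest

from koperator import (
    SquareMatrix,
    k_kernel,
    k_matrix_product,
    k_mixed,
    k_ratio,
    t_matrix,
)
from koperator.operators import median_row_bandwidth


class TestKMatrixProduct:
    def test_no_change_gives_identity(self, g_pair):
        _, g = g_pair
        k = k_matrix_product(g, g)
        np.testing.assert_allclose(k.values, np.eye(2), atol=1e-12)

    def test_hand_2x2(self, g_pair):
        gk, g = g_pair
        k = k_matrix_product(gk, g)
        np.testing.assert_allclose(
            k.values, np.array([[1.2, -0.4], [-0.4, 1.2]]), atol=1e-12
        )

    def test_symbolic_entries(self, rng):
        # K^@ entries are [[f m + x o, f n + x p], [x m + c o, x n + c p]]
        # for gk = [[f, x], [x, c]] and inverse entries [[m, n], [o, p]]
        fk, ck, xk = rng.uniform(0.1, 1, 3)
        gk = SquareMatrix(np.array([[fk, xk], [xk, ck]]))
        g = SquareMatrix(np.array([[1.0, 0.3], [0.3, 1.0]]))
        m, n_, o, p = np.linalg.inv(g.values).ravel()
        expected = np.array(
            [[fk * m + xk * o, fk * n_ + xk * p],
             [xk * m + ck * o, xk * n_ + ck * p]]
        )
        np.testing.assert_allclose(
            k_matrix_product(gk, g).values, expected, atol=1e-12
        )

    def test_applying_k_recovers_gk(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            g = SquareMatrix(r.uniform(0.1, 1, (4, 4)) + 4 * np.eye(4))
            gk = SquareMatrix(r.uniform(0, 1, (4, 4)))
            k = k_matrix_product(gk, g)
            resid = np.max(np.abs(k.values @ g.values - gk.values))
            assert resid <= 1e-8 * np.max(np.abs(gk.values))

    def test_label_mismatch_rejected(self, g_pair):
        gk, g = g_pair
        other = SquareMatrix(g.values, labels=("x", "y"))
        with pytest.raises(ValueError, match="label"):
            k_matrix_product(gk, other)


class TestKMixed:
    def test_identity_reference_keeps_only_diagonal(self, g_pair):
        gk, _ = g_pair
        ident = SquareMatrix(np.eye(2))
        k = k_mixed(gk, ident)
        np.testing.assert_allclose(k.values, np.diag(np.diag(gk.values)))

    def test_hand_2x2(self, g_pair):
        gk, g = g_pair
        k = k_mixed(gk, g)
        np.testing.assert_allclose(
            k.values,
            np.array([[4 / 3, -2 / 15], [-2 / 15, 4 / 3]]),
            atol=1e-12,
        )

    def test_symbolic_entries(self, rng):
        # K^* entries are [[f m, x n], [x o, c p]]
        fk, ck, xk = rng.uniform(0.1, 1, 3)
        gk = SquareMatrix(np.array([[fk, xk], [xk, ck]]))
        g = SquareMatrix(np.array([[1.0, 0.3], [0.3, 1.0]]))
        m, n_, o, p = np.linalg.inv(g.values).ravel()
        expected = np.array([[fk * m, xk * n_], [xk * o, ck * p]])
        np.testing.assert_allclose(k_mixed(gk, g).values, expected, atol=1e-12)

    def test_symmetric_inputs_give_symmetric_k(self, rng):
        from koperator import make_random_symmetric

        for seed in range(5):
            g = make_random_symmetric(5, (0.1, 1.0), seed=seed)
            gk = make_random_symmetric(5, (0.0, 1.0), seed=seed + 100)
            k = k_mixed(gk, g)
            np.testing.assert_allclose(k.values, k.values.T, atol=1e-10)


class TestKRatio:
    def test_self_ratio_is_all_ones(self, random_connectome):
        k = k_ratio(random_connectome, random_connectome)
        np.testing.assert_allclose(k.values, np.ones((6, 6)))

    def test_elementwise_division(self):
        prev = SquareMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]))
        nxt = SquareMatrix(np.array([[1.0, 0.25], [0.25, 1.0]]))
        k = k_ratio(nxt, prev)
        np.testing.assert_allclose(
            k.values, np.array([[1.0, 0.5], [0.5, 1.0]])
        )

    def test_zero_denominator_uses_floor_with_positive_sign(self):
        prev = SquareMatrix(np.array([[1.0, 0.0], [0.0, 1.0]]))
        nxt = SquareMatrix(np.array([[1.0, 0.3], [0.3, 1.0]]))
        k = k_ratio(nxt, prev, zero_floor=1e-6)
        assert k.values[0, 1] == pytest.approx(3e5)

    def test_negative_denominator_keeps_sign(self):
        prev = SquareMatrix(np.array([[1.0, -0.5], [-0.5, 1.0]]))
        nxt = SquareMatrix(np.array([[1.0, 0.25], [0.25, 1.0]]))
        k = k_ratio(nxt, prev)
        assert k.values[0, 1] == pytest.approx(-0.5)

    def test_composition_along_time(self, rng):
        # K(G2, G1) * K(G1, G0) = K(G2, G0) element-wise when no floor fires
        mats = [
            SquareMatrix(rng.uniform(0.1, 1.0, (4, 4))) for _ in range(3)
        ]
        k10 = k_ratio(mats[1], mats[0])
        k21 = k_ratio(mats[2], mats[1])
        k20 = k_ratio(mats[2], mats[0])
        np.testing.assert_allclose(k21.values * k10.values, k20.values, rtol=1e-12)

    def test_never_divides_by_zero(self):
        prev = SquareMatrix(np.zeros((3, 3)))
        nxt = SquareMatrix(np.full((3, 3), 0.5))
        k = k_ratio(nxt, prev)
        assert np.all(np.isfinite(k.values))


class TestKKernel:
    def test_identical_inputs_have_unit_diagonal(self, random_connectome):
        k = k_kernel(random_connectome, random_connectome)
        np.testing.assert_allclose(np.diag(k.values), np.ones(6))

    def test_entries_in_unit_interval(self, rng):
        gk = SquareMatrix(rng.uniform(-1, 1, (5, 5)))
        g = SquareMatrix(rng.uniform(-1, 1, (5, 5)))
        k = k_kernel(gk, g, bandwidth=0.7)
        assert np.all(k.values > 0) and np.all(k.values <= 1)

    def test_matches_naive_double_loop(self, rng):
        gk = SquareMatrix(rng.uniform(0, 1, (3, 3)))
        g = SquareMatrix(rng.uniform(0, 1, (3, 3)))
        bw = 0.5
        k = k_kernel(gk, g, bandwidth=bw)
        for i in range(3):
            for j in range(3):
                d2 = np.sum((gk.values[i] - g.values[j]) ** 2)
                assert k.values[i, j] == pytest.approx(
                    np.exp(-d2 / (2 * bw**2)), rel=1e-12
                )

    def test_median_heuristic_default(self, rng):
        gk = SquareMatrix(rng.uniform(0, 1, (4, 4)))
        g = SquareMatrix(rng.uniform(0, 1, (4, 4)))
        assert median_row_bandwidth(gk, g) > 0
        k = k_kernel(gk, g)  # default bandwidth must work
        assert np.all(k.values > 0)

    def test_non_positive_bandwidth_rejected(self, g_pair):
        gk, g = g_pair
        with pytest.raises(ValueError, match="bandwidth"):
            k_kernel(gk, g, bandwidth=0.0)


class TestTMatrix:
    def test_diagonal_inputs_give_zero_t(self):
        gk = SquareMatrix(np.diag([2.0, 3.0]))
        g = SquareMatrix(np.diag([1.0, 0.5]))
        t = t_matrix(gk, g)
        np.testing.assert_allclose(t.values, np.zeros((2, 2)), atol=1e-12)

    def test_hand_2x2(self, g_pair):
        gk, g = g_pair
        t = t_matrix(gk, g)
        np.testing.assert_allclose(
            t.values,
            np.array([[-2 / 15, -4 / 15], [-4 / 15, -2 / 15]]),
            atol=1e-12,
        )

    def test_symbolic_entries(self, rng):
        # T = [[x o, f n + x p - x n], [x m + c o - x o, x n]]
        fk, ck, xk = rng.uniform(0.1, 1, 3)
        gk = SquareMatrix(np.array([[fk, xk], [xk, ck]]))
        g = SquareMatrix(np.array([[1.0, 0.4], [0.4, 1.0]]))
        m, n_, o, p = np.linalg.inv(g.values).ravel()
        expected = np.array(
            [[xk * o, fk * n_ + xk * p - xk * n_],
             [xk * m + ck * o - xk * o, xk * n_]]
        )
        np.testing.assert_allclose(t_matrix(gk, g).values, expected, atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_additivity_exact(self, seed):
        rng = np.random.default_rng(seed)
        g = SquareMatrix(rng.uniform(0.1, 1, (5, 5)) + 5 * np.eye(5))
        gk = SquareMatrix(rng.uniform(0, 1, (5, 5)))
        ka = k_matrix_product(gk, g).values
        ks = k_mixed(gk, g).values
        t = t_matrix(gk, g).values
        assert np.max(np.abs(ka - (ks + t))) <= 1e-12
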