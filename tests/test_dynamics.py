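import numpy as np
import pytest

from koperator import (
    DynamicsSeries,
    SquareMatrix,
    classify_dynamics,
    evolve_k,
    extract_pair_series,
    fit_linear,
    fit_quadratic,
    k_ratio,
    make_random_symmetric,
    select_roi_pairs,
    simulate_model,
)


class TestSimulateModel:
    def test_increasing_entries_strictly_increase(self):
        s = simulate_model("increasing", seed=7)
        stack = s.stack()
        assert np.all(np.diff(stack, axis=0) > 0)

    def test_decreasing_entries_stay_positive(self):
        # worst case: 0.55 - 9 * 0.05 = 0.10 > 0
        for seed in range(10):
            s = simulate_model("decreasing", seed=seed)
            assert np.all(s.stack() > 0)
            assert np.all(np.diff(s.stack(), axis=0) < 0)

    def test_varying_rises_then_falls(self):
        s = simulate_model("varying", steps=10, seed=3)
        stack = s.stack()
        diffs = np.diff(stack, axis=0)
        assert np.all(diffs[:5] > 0) and np.all(diffs[5:] < 0)

    def test_null_differs_across_seeds(self):
        a = simulate_model("null", seed=1)
        b = simulate_model("null", seed=2)
        assert not np.array_equal(a.stack(), b.stack())

    def test_deterministic_under_seed(self):
        a = simulate_model("increasing", seed=4)
        b = simulate_model("increasing", seed=4)
        np.testing.assert_array_equal(a.stack(), b.stack())

    def test_matrices_symmetric_and_time_labels_natural(self):
        s = simulate_model("null", steps=10, seed=0)
        assert s.time_labels == tuple(float(t) for t in range(1, 11))
        for m in s.matrices:
            np.testing.assert_array_equal(m.values, m.values.T)

    def test_impossible_decrease_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            simulate_model("decreasing", steps=10, delta_range=(0.05, 0.1),
                           init_range=(0.5, 1.0), seed=0)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            simulate_model("sideways", seed=0)


class TestEvolveK:
    def test_increasing_model_k_at_least_one(self):
        for seed in range(20):
            traj = evolve_k(simulate_model("increasing", seed=seed))
            assert traj.element_range[0] >= 1.0

    def test_decreasing_model_k_in_unit_interval(self):
        for seed in range(20):
            traj = evolve_k(simulate_model("decreasing", seed=seed))
            lo, hi = traj.element_range
            assert lo > 0.0 and hi < 1.0

    def test_constant_series_gives_all_ones(self, random_connectome):
        series = DynamicsSeries(matrices=(random_connectome,) * 3)
        traj = evolve_k(series)
        assert len(traj) == 2
        for k in traj.k_matrices:
            np.testing.assert_allclose(k.values, np.ones((6, 6)))

    def test_trajectory_length(self):
        s = simulate_model("null", steps=10, seed=0)
        assert len(evolve_k(s)) == 9


class TestClassifyDynamics:
    @pytest.mark.parametrize("model", ["increasing", "decreasing", "varying"])
    def test_recovers_generating_model_over_seeds(self, model):
        hits = sum(
            classify_dynamics(evolve_k(simulate_model(model, seed=seed))) == model
            for seed in range(50)
        )
        assert hits == 50

    def test_all_ones_boundary_is_null(self, random_connectome):
        series = DynamicsSeries(matrices=(random_connectome,) * 3)
        assert classify_dynamics(evolve_k(series)) == "null"


class TestRegressionFits:
    @staticmethod
    def _series_from_scalar(points):
        mats = tuple(
            SquareMatrix(np.full((2, 2), y), labels=("a", "b")) for _, y in points
        )
        return DynamicsSeries(
            matrices=mats, time_labels=tuple(t for t, _ in points)
        )

    def test_linear_hand_computation(self):
        s = self._series_from_scalar([(1, 0.1), (2, 0.4), (3, 0.9)])
        fit = fit_linear(s)
        a, b = fit.element(0, 1)
        assert a == pytest.approx(0.4, abs=1e-10)
        assert b == pytest.approx(-1 / 3, abs=1e-10)

    def test_quadratic_interpolates_three_points(self):
        s = self._series_from_scalar([(1, 0.1), (2, 0.4), (3, 0.9)])
        fit = fit_quadratic(s)
        a, b, c = fit.element(0, 1)
        assert a == pytest.approx(0.1, abs=1e-10)
        assert b == pytest.approx(0.0, abs=1e-10)
        assert c == pytest.approx(0.0, abs=1e-10)
        assert np.max(fit.residual_sse) <= 1e-10

    def test_constant_trajectory_is_flat(self):
        s = self._series_from_scalar([(1, 0.7), (2, 0.7), (3, 0.7), (4, 0.7)])
        fit = fit_linear(s)
        a, b = fit.element(1, 0)
        assert a == pytest.approx(0.0, abs=1e-12)
        assert b == pytest.approx(0.7, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        s = simulate_model("varying", n=3, steps=8, seed=5)
        fit = fit_linear(s)
        t = np.asarray(s.time_labels)
        x = np.column_stack([t, np.ones_like(t)])
        xtx_inv = np.linalg.inv(x.T @ x)
        for i in range(3):
            for j in range(3):
                y = s.stack()[:, i, j]
                coef = xtx_inv @ (x.T @ y)
                np.testing.assert_allclose(fit.element(i, j), coef, atol=1e-10)

    def test_predict_evaluates_polynomial(self):
        s = self._series_from_scalar([(1, 0.1), (2, 0.4), (3, 0.9)])
        fit = fit_quadratic(s)
        np.testing.assert_allclose(fit.predict(2.0), np.full((2, 2), 0.4),
                                   atol=1e-10)

    def test_too_few_points_rejected(self):
        s = self._series_from_scalar([(1, 0.1), (2, 0.4)])
        with pytest.raises(ValueError, match="at least 3"):
            fit_quadratic(s)


class TestSelectRoiPairs:
    def test_single_dominant_pair(self):
        k = k_ratio(
            SquareMatrix(np.array([[1.0, 5.0], [5.0, 1.0]]), labels=("u", "v")),
            SquareMatrix(np.array([[1.0, 1.0], [1.0, 1.0]]), labels=("u", "v")),
        )
        assert select_roi_pairs(k, top_n=1) == [("u", "v", 5.0)]

    def test_diagonal_never_returned(self):
        m = SquareMatrix(np.diag([9.0, 9.0, 9.0]) + 0.1)
        pairs = select_roi_pairs(m, top_n=3)
        assert all(a != b for a, b, _ in pairs)

    def test_matches_brute_force_sort(self, rng):
        m = SquareMatrix(rng.uniform(-2, 2, (6, 6)))
        pairs = select_roi_pairs(m, top_n=15)
        brute = sorted(
            (
                (m.labels[i], m.labels[j], float(m.values[i, j]))
                for i in range(6)
                for j in range(i + 1, 6)
            ),
            key=lambda p: -abs(p[2]),
        )
        assert [abs(v) for *_, v in pairs] == [abs(v) for *_, v in brute]

    def test_excess_top_n_truncates_with_warning(self, random_connectome):
        with pytest.warns(UserWarning, match="only 15"):
            pairs = select_roi_pairs(random_connectome, top_n=99)
        assert len(pairs) == 15


class TestExtractPairSeries:
    def test_connectivity_diagonals_stay_one(self):
        mats = tuple(
            make_random_symmetric(5, (0.0, 1.0), seed=s) for s in range(3)
        )
        series = DynamicsSeries(matrices=mats)
        sub = extract_pair_series(series, "ROI2", "ROI4")
        for m in sub.matrices:
            np.testing.assert_array_equal(np.diag(m.values), np.ones(2))

    def test_off_diagonal_matches_source(self):
        mats = tuple(
            make_random_symmetric(5, (0.0, 1.0), seed=s) for s in range(3)
        )
        series = DynamicsSeries(matrices=mats)
        sub = extract_pair_series(series, "ROI1", "ROI3")
        for orig, s in zip(mats, sub.matrices):
            assert s.values[0, 1] == orig.values[0, 2]

    def test_idempotent(self):
        mats = tuple(
            make_random_symmetric(4, (0.0, 1.0), seed=s) for s in range(2)
        )
        series = DynamicsSeries(matrices=mats)
        once = extract_pair_series(series, "ROI1", "ROI2")
        twice = extract_pair_series(once, "ROI1", "ROI2")
        np.testing.assert_array_equal(once.stack(), twice.stack())

    def test_unknown_label_rejected(self):
        mats = tuple(
            make_random_symmetric(4, (0.0, 1.0), seed=s) for s in range(2)
        )
        with pytest.raises(KeyError, match="nope"):
            extract_pair_series(DynamicsSeries(matrices=mats), "ROI1", "nope")
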