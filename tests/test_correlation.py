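"""Shifted PC, ridge regression, cross-validated MPC: oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import msamap as m
from msamap.correlation import EventTrain, make_fold_plan
from msamap.features import DegenerateInputError, TFFeatures

STEP = 0.05


def event_train(y, step=STEP):
    y = np.asarray(y, dtype=np.int8)
    ft = step * (np.arange(y.size) + 3)
    return EventTrain(onset_times=ft[y == 1], y=y, frame_times=ft, step=step)


def features_from(values, channel_locus, step=STEP):
    values = np.asarray(values, dtype=float)
    ft = step * (np.arange(values.shape[0]) + 3)
    return TFFeatures(values=values, frame_times=ft, window=0.3, step=step,
                      channel_locus=np.asarray(channel_locus))


def ridge_oracle(X, y, lam):
    """Direct normal-equations arithmetic on standardized columns."""
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Z = (X - mu) / sd
    b = np.linalg.inv(Z.T @ Z + lam * np.eye(X.shape[1])) @ (Z.T @ (y - y.mean()))
    b = b / sd
    return b, y.mean() - mu @ b


class TestFrameEventTrain:
    def test_onsets_at_frame_centers(self):
        feats = features_from(np.zeros((20, 1, 1)), [0])
        onsets = feats.frame_times[[2, 7, 11]]
        ev = m.frame_event_train(onsets, feats)
        assert ev.y.sum() == 3
        assert list(np.flatnonzero(ev.y)) == [2, 7, 11]

    def test_midpoint_tie_goes_to_earlier_frame(self):
        feats = features_from(np.zeros((20, 1, 1)), [0])
        onset = (feats.frame_times[4] + feats.frame_times[5]) / 2
        ev = m.frame_event_train([onset], feats)
        assert list(np.flatnonzero(ev.y)) == [4]

    def test_nearest_frame_matches_exhaustive_search(self):
        feats = features_from(np.zeros((30, 1, 1)), [0])
        rng = np.random.default_rng(0)
        onsets = rng.uniform(feats.frame_times[0], feats.frame_times[-1], 10)
        ev = m.frame_event_train(onsets, feats)
        expected = {int(np.abs(feats.frame_times - t).argmin()) for t in onsets}
        assert set(np.flatnonzero(ev.y)) == expected

    def test_out_of_range_onsets_dropped_and_counted(self):
        feats = features_from(np.zeros((20, 1, 1)), [0])
        with pytest.warns(UserWarning, match="dropped 2"):
            ev = m.frame_event_train([-5.0, feats.frame_times[3], 99.0], feats)
        assert ev.n_dropped == 2
        assert ev.y.sum() == 1

    def test_no_onset_in_range_rejected(self):
        feats = features_from(np.zeros((20, 1, 1)), [0])
        with pytest.raises(ValueError):
            m.frame_event_train([99.0], feats)


class TestShiftedPC:
    def test_self_correlation_is_one(self):
        ev = event_train([0, 1, 0, 0, 1, 0, 0, 0])
        xf = ev.y - ev.y_mean
        curve = m.shifted_pc(xf, ev, [0.0])
        assert curve.values[0] == pytest.approx(1.0)

    def test_shift_identity_recovers_lag(self):
        y = np.zeros(40, dtype=int)
        y[[5, 14, 23, 31]] = 1
        ev = event_train(y)
        k = 4
        xf = np.roll(y, k).astype(float)  # xf(t) = y(t - k)
        xf[:k] = 0
        shifts = STEP * np.arange(0, 8)
        curve = m.shifted_pc(xf - xf.mean(), ev, shifts)
        assert curve.shifts[curve.values.argmax()] == pytest.approx(k * STEP)

    def test_matches_hand_evaluation_on_toy_series(self):
        xf = np.array([0, 1, 2, 0, 0, 3, 1, 0], dtype=float)
        y = np.array([0, 0, 1, 0, 0, 0, 1, 0])
        ev = event_train(y)
        curve = m.shifted_pc(xf, ev, [0.0])
        # oracle: direct evaluation of the correlation sum
        expected = np.corrcoef(xf, y)[0, 1]
        assert curve.values[0] == pytest.approx(expected, abs=1e-12)
        assert curve.values[0] == pytest.approx(0.34259, abs=1e-4)

    def test_zero_variance_rejected(self):
        ev = event_train([0, 1, 0, 1])
        with pytest.raises(DegenerateInputError):
            m.shifted_pc(np.ones(4), ev, [0.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 50.0), st.floats(-5.0, 5.0))
    def test_invariant_under_positive_affine_transform(self, seed, a, b):
        rng = np.random.default_rng(seed)
        xf = rng.standard_normal(30)
        y = np.zeros(30, dtype=int)
        y[rng.choice(30, 5, replace=False)] = 1
        ev = event_train(y)
        shifts = STEP * np.arange(-3, 4)
        r0 = m.shifted_pc(xf, ev, shifts).values
        r_pos = m.shifted_pc(a * xf + b, ev, shifts).values
        r_neg = m.shifted_pc(-a * xf + b, ev, shifts).values
        np.testing.assert_allclose(r_pos, r0, atol=1e-9)
        np.testing.assert_allclose(r_neg, -r0, atol=1e-9)
        assert (np.abs(r0) <= 1.0).all()


class TestDesignMatrix:
    def test_doublet_times_thirty_bands_gives_sixty_predictors(self):
        rng = np.random.default_rng(3)
        feats = features_from(rng.random((50, 2, 30)), [0, 0])
        X = m.build_design_matrix(feats, 0)
        assert X.p == 60
        assert X.n == 50

    def test_column_map_is_bijection_channel_major(self):
        rng = np.random.default_rng(4)
        feats = features_from(rng.random((20, 4, 3)), [0, 0, 1, 1])
        X = m.build_design_matrix(feats, 1)
        assert X.column_map == tuple((c, b) for c in (2, 3) for b in (0, 1, 2))
        for col, (c, b) in enumerate(X.column_map):
            np.testing.assert_array_equal(X.X[:, col], feats.values[:, c, b])

    def test_single_channel_single_band(self):
        rng = np.random.default_rng(5)
        feats = features_from(rng.random((20, 1, 1)), [0])
        X = m.build_design_matrix(feats, 0)
        assert X.p == 1
        np.testing.assert_array_equal(X.X[:, 0], feats.values[:, 0, 0])

    def test_empty_band_subset_rejected(self):
        feats = features_from(np.random.default_rng(0).random((10, 1, 2)), [0])
        with pytest.raises(ValueError):
            m.build_design_matrix(feats, 0, band_subset=[])


class TestRidgeFit:
    def test_zero_penalty_equals_ordinary_least_squares(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((40, 3))
        y = rng.standard_normal(40)
        model = m.ridge_fit(X, y, 0.0)
        A = np.column_stack([np.ones(40), X])
        coef = np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(model.b, coef[1:], atol=1e-10)
        assert model.intercept == pytest.approx(coef[0], abs=1e-10)

    def test_infinite_penalty_shrinks_to_target_mean(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        model = m.ridge_fit(X, y, 1e12)
        np.testing.assert_allclose(model.b, 0.0, atol=1e-9)
        np.testing.assert_allclose(model.predict(X), y.mean(), atol=1e-6)

    def test_toy_system_matches_normal_equations(self):
        X = np.array([[1.0, 2.0], [3.0, 1.0], [2.0, 4.0]])
        y = np.array([1.0, 2.0, 0.5])
        model = m.ridge_fit(X, y, 1.0)
        b, intercept = ridge_oracle(X, y, 1.0)
        np.testing.assert_allclose(model.b, b, atol=1e-12)
        assert model.intercept == pytest.approx(intercept, abs=1e-12)

    def test_matches_oracle_on_random_systems(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            X = rng.standard_normal((10, 5))
            y = rng.standard_normal(10)
            lam = rng.uniform(0.0, 5.0)
            model = m.ridge_fit(X, y, lam)
            b, intercept = ridge_oracle(X, y, lam)
            scale = np.abs(b).max()
            assert np.abs(model.b - b).max() < 1e-10 * max(scale, 1.0)
            assert abs(model.intercept - intercept) < 1e-10 * max(scale, 1.0)

    def test_rank_deficient_ols_advises_regularization(self):
        rng = np.random.default_rng(9)
        col = rng.standard_normal(20)
        X = np.column_stack([col, col])
        with pytest.raises(np.linalg.LinAlgError, match="lam"):
            m.ridge_fit(X, rng.standard_normal(20), 0.0)


class TestCvPredict:
    def test_four_folds_of_eight_frames(self):
        plan = make_fold_plan(8, 4)
        _, counts = np.unique(plan.assignment, return_counts=True)
        assert list(counts) == [2, 2, 2, 2]
        rng = np.random.default_rng(10)
        pred = m.cv_predict(rng.standard_normal((8, 2)),
                            rng.standard_normal(8), plan, 1.0)
        assert pred.shape == (8,)

    def test_fold_plan_contiguous_exact_cover(self):
        plan = make_fold_plan(103, 4)
        assert plan.assignment.size == 103
        assert (np.diff(plan.assignment) >= 0).all()  # contiguous blocks
        assert set(plan.assignment) == {0, 1, 2, 3}

    def test_matches_manual_half_fits(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((4, 1))
        y = rng.standard_normal(4)
        pred = m.cv_predict(X, y, make_fold_plan(4, 2), 0.0)
        # oracle: explicit per-fold OLS
        for test_rows, train_rows in (([0, 1], [2, 3]), ([2, 3], [0, 1])):
            A = np.column_stack([np.ones(2), X[train_rows, 0]])
            coef = np.linalg.lstsq(A, y[train_rows], rcond=None)[0]
            expected = coef[0] + coef[1] * X[test_rows, 0]
            np.testing.assert_allclose(pred[test_rows], expected, atol=1e-10)

    def test_constant_target_predicted_exactly(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((20, 3))
        pred = m.cv_predict(X, np.full(20, 2.5), make_fold_plan(20, 4), 1.0)
        np.testing.assert_allclose(pred, 2.5, atol=1e-9)


class TestCvMpc:
    def test_single_predictor_reduces_to_shifted_pc(self):
        rng = np.random.default_rng(13)
        y = np.zeros(60, dtype=int)
        y[rng.choice(60, 8, replace=False)] = 1
        ev = event_train(y)
        xf = rng.standard_normal(60) + 3 * np.roll(y, 2)
        for tau in (0.0, STEP, 2 * STEP):
            r_multi = m.cv_mpc(xf[:, None], ev, tau, 1, 0.0)
            r_simple = m.shifted_pc(xf, ev, [tau]).values[0]
            assert r_multi == pytest.approx(abs(r_simple), abs=1e-12)

    def test_independent_noise_gives_near_zero_correlation(self):
        n = 400
        rs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = np.zeros(n, dtype=int)
            y[rng.choice(n, 40, replace=False)] = 1
            X = rng.standard_normal((n, 5))
            rs.append(m.cv_mpc(X, event_train(y), 0.0, 4, 1.0))
        assert np.mean(np.abs(rs)) < 3 / np.sqrt(n)

    def test_sixty_predictor_toy_matches_composed_oracles(self):
        rng = np.random.default_rng(14)
        n, p = 240, 60
        y = np.zeros(n, dtype=int)
        y[rng.choice(n, 30, replace=False)] = 1
        X = rng.standard_normal((n, p))
        X[:, 7] += 2.0 * y
        X[:, 31] -= 1.5 * y
        ev = event_train(y)
        r = m.cv_mpc(X, ev, 0.0, 4, 1.0)
        # reference built from the ridge and per-fold oracles
        plan = make_fold_plan(n, 4)
        pred = np.empty(n)
        for fold in range(4):
            test = plan.assignment == fold
            b, c = ridge_oracle(X[~test], y[~test].astype(float), 1.0)
            pred[test] = X[test] @ b + c
        expected = np.corrcoef(pred, y)[0, 1]
        assert r == pytest.approx(expected, abs=1e-10)
        assert abs(r - expected) < 0.02

    def test_in_sample_fit_exceeds_cross_validated_fit_on_noise(self):
        # the overfitting that motivates cross-validation
        n, p = 150, 30
        gap = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = np.zeros(n, dtype=int)
            y[rng.choice(n, 15, replace=False)] = 1
            X = rng.standard_normal((n, p))
            ev = event_train(y)
            r_in = m.cv_mpc(X, ev, 0.0, 1, 1.0)
            r_cv = m.cv_mpc(X, ev, 0.0, 4, 1.0)
            gap.append(r_in - r_cv)
        assert np.mean(gap) > 0

    def test_degenerate_shifted_target_rejected(self):
        y = np.zeros(30, dtype=int)
        y[28] = 1
        ev = event_train(y)
        X = np.random.default_rng(15).standard_normal((30, 2))
        with pytest.raises(DegenerateInputError):
            m.cv_mpc(X, ev, 28 * STEP, 2, 1.0)


class TestMsaMap:
    def test_deterministic_and_curve_shape(self):
        rng = np.random.default_rng(16)
        feats = features_from(rng.standard_normal((120, 4, 3)), [0, 0, 1, 1])
        y = np.zeros(120, dtype=int)
        y[::12] = 1
        ev = event_train(y)
        shifts = STEP * np.arange(0, 6)
        m1 = m.msa_map(feats, ev, shifts, n_folds=4, lam=1.0)
        m2 = m.msa_map(feats, ev, shifts, n_folds=4, lam=1.0)
        np.testing.assert_array_equal(m1.values, m2.values)
        assert m1.values.shape == (2, 6)
        assert np.nanmax(np.abs(m1.values)) <= 1.0

    def test_degenerate_locus_flagged_not_fatal(self):
        rng = np.random.default_rng(17)
        vals = rng.standard_normal((100, 4, 2))
        vals[:, 3, :] = vals[:, 2, :]  # locus 1 channels identical -> singular OLS
        feats = features_from(vals, [0, 0, 1, 1])
        y = np.zeros(100, dtype=int)
        y[::10] = 1
        mpc = m.msa_map(feats, event_train(y), STEP * np.arange(3),
                        n_folds=2, lam=0.0)
        assert mpc.degenerate[1]
        assert not mpc.degenerate[0]
        assert np.isfinite(mpc.values[0]).all()
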