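"""Ridge-with-history, classifier, and split machinery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as spstats

from synbmi.decoding import (RidgeDecoder, build_history_design,
                             chronological_split, classify, fit_classifier,
                             fit_ridge, fit_ridge_cv, macro_accuracy,
                             pearson_cc, predict_and_score, trial_bin_mask)
from synbmi.session import BinnedSession, TrialTable


class TestHistoryDesign:
    def test_shape_arithmetic(self):
        X = np.random.default_rng(0).normal(size=(50, 3))
        d, t = build_history_design(X, lags=10)
        assert d.shape == (40, 31)
        assert t[0] == 10 and t[-1] == 49

    def test_single_lag_is_intercept_plus_current(self):
        X = np.arange(12.0).reshape(6, 2)
        d, t = build_history_design(X, lags=1)
        assert np.allclose(d[:, 0], 1.0)
        assert np.allclose(d[:, 1:], X[1:])

    def test_masked_bin_removes_touching_rows(self):
        X = np.random.default_rng(1).normal(size=(50, 2))
        mask = np.zeros(50, dtype=bool)
        mask[20] = True
        _, t = build_history_design(X, lags=10, mask=mask)
        gone = set(range(20, 30))
        assert gone.isdisjoint(t.tolist())
        assert set(range(10, 20)) <= set(t.tolist())

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            build_history_design(np.zeros((5, 2)), lags=10)


class TestRidge:
    def test_exact_lagged_relation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(200, 1))
        y = np.zeros(200)
        y[1:] = 2.0 * x[:-1, 0]
        design, t = build_history_design(x, lags=2)
        dec = fit_ridge(design, y[t], 0.0, lags=2)
        # columns: [1, x_t, x_{t-1}]
        assert dec.weights[2, 0] == pytest.approx(2.0, abs=1e-8)
        cc = pearson_cc(y[t], design @ dec.weights[:, 0])
        assert cc[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(3)
        design = np.column_stack([np.ones(50),
                                  rng.normal(size=(50, 3))])
        Y = rng.normal(size=(50, 2))
        lam = 0.7
        dec = fit_ridge(design, Y, lam, lags=1)
        pen = np.diag([0.0, 1.0, 1.0, 1.0])
        W = np.linalg.solve(design.T @ design + lam * pen, design.T @ Y)
        assert np.allclose(dec.weights, W, atol=1e-8)

    def test_huge_lambda_shrinks_to_output_means(self):
        rng = np.random.default_rng(4)
        design = np.column_stack([np.ones(100), rng.normal(size=(100, 2))])
        Y = rng.normal(loc=3.0, size=(100, 2))
        dec = fit_ridge(design, Y, 1e12, lags=1)
        pred = design @ dec.weights
        assert np.allclose(pred, Y.mean(axis=0), atol=1e-3)

    def test_rank_deficient_without_penalty_rejected(self):
        X = np.ones((10, 3))            # duplicated columns
        with pytest.raises(np.linalg.LinAlgError, match="lambda"):
            fit_ridge(X, np.zeros(10), 0.0, lags=1)

    @given(st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_scale_consistency_at_zero_lambda(self, c):
        rng = np.random.default_rng(5)
        design = np.column_stack([np.ones(40), rng.normal(size=(40, 2))])
        Y = rng.normal(size=40)
        base = fit_ridge(design, Y, 0.0, lags=1)
        scaled_design = design.copy()
        scaled_design[:, 1] *= c
        scaled = fit_ridge(scaled_design, Y, 0.0, lags=1)
        assert scaled.weights[1, 0] == pytest.approx(base.weights[1, 0] / c,
                                                     rel=1e-8)

    def test_cv_is_deterministic(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(300, 4))
        Y = X @ rng.normal(size=(4, 2)) + 0.1 * rng.normal(size=(300, 2))
        design, t = build_history_design(X, lags=3)
        d1 = fit_ridge_cv(design, Y[t], lags=3)
        d2 = fit_ridge_cv(design, Y[t], lags=3)
        assert d1.lam == d2.lam
        assert np.array_equal(d1.weights, d2.weights)


class TestPearson:
    def test_perfect_and_anticorrelated(self):
        y = np.arange(10.0)[:, None]
        assert pearson_cc(y, y)[0] == pytest.approx(1.0)
        assert pearson_cc(y, -y)[0] == pytest.approx(-1.0)

    def test_hand_case_matches_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 6.0, 8.1])
        expected = spstats.pearsonr(x, y).statistic
        assert pearson_cc(x, y)[0] == pytest.approx(expected, abs=1e-12)

    def test_constant_series_scores_zero(self, caplog):
        with caplog.at_level("WARNING"):
            cc = pearson_cc(np.ones(5), np.arange(5.0))
        assert cc[0] == 0.0
        assert "constant" in caplog.text

    def test_predict_and_score_roundtrip(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(100, 2))
        Y = X @ np.array([[1.0], [2.0]])
        design, t = build_history_design(X, lags=2)
        dec = fit_ridge(design, Y[t], 1e-8, lags=2)
        cc = predict_and_score(dec, X, Y)
        assert cc[0] == pytest.approx(1.0, abs=1e-6)


class TestClassifier:
    def _clusters(self, sd, n_per=12, seed=0):
        rng = np.random.default_rng(seed)
        centers = np.stack(np.meshgrid(np.arange(3.0), np.arange(3.0)),
                           axis=-1).reshape(9, 2)
        feats, labels = [], []
        for k, c in enumerate(centers, start=1):
            feats.append(c + sd * rng.normal(size=(n_per, 2)))
            labels.append(np.full(n_per, k))
        return np.concatenate(feats), np.concatenate(labels)

    def test_separable_clusters_perfect(self):
        feats, labels = self._clusters(sd=0.01)
        clf = fit_classifier(feats, labels, seed=0)
        assert macro_accuracy(labels, classify(clf, feats)) == 1.0

    def test_shuffled_labels_near_chance(self):
        feats, labels = self._clusters(sd=0.01, n_per=30, seed=1)
        rng = np.random.default_rng(11)
        shuffled = rng.permutation(labels)
        clf = fit_classifier(feats, shuffled, seed=0)
        acc = macro_accuracy(shuffled, classify(clf, feats))
        n = len(labels)
        band = 1.96 * np.sqrt((1 / 9) * (8 / 9) / n)
        assert abs(acc - 1 / 9) < 3 * band + 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_classifier(np.zeros((5, 2)), np.ones(5))

    def test_absent_test_class_skipped_with_warning(self):
        y_true = np.array([1, 1, 2, 2])
        y_pred = np.array([1, 1, 2, 1])
        with pytest.warns(UserWarning, match="absent"):
            acc = macro_accuracy(y_true, y_pred, all_classes=np.arange(1, 10))
        assert acc == pytest.approx((1.0 + 0.5) / 2)


def _trials(n):
    starts = np.arange(n) * 10
    return TrialTable(start_bin=starts, end_bin=starts + 10,
                      target=np.tile([1, 5], n)[:n],
                      context=np.array(["normal"] * n, dtype=object),
                      artifact_start=starts, artifact_end=starts + 2)


class TestSplit:
    def test_ten_trials_80_20(self):
        train, test = chronological_split(_trials(10), 0.8)
        assert train.tolist() == list(range(8))
        assert test.tolist() == [8, 9]

    def test_full_train_fraction_rejected(self):
        with pytest.raises(ValueError):
            chronological_split(_trials(10), 1.0)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            chronological_split(_trials(4), 0.8)

    def test_bin_sets_disjoint_and_exclude_masked(self):
        tr = _trials(10)
        T = 100
        mask = np.zeros(T, dtype=bool)
        for i in range(10):
            mask[tr.artifact_start[i]:tr.artifact_end[i]] = True
        sess = BinnedSession(neural=np.zeros((T, 2)), emg=np.zeros((T, 1)),
                             kinematics=np.zeros((T, 4)), trials=tr,
                             bin_width=0.02, artifact_mask=mask)
        train, test = chronological_split(tr, 0.8)
        m_train = trial_bin_mask(sess, train)
        m_test = trial_bin_mask(sess, test)
        assert not np.any(m_train & m_test)
        assert not np.any(m_train & mask) and not np.any(m_test & mask)


def test_rotation_invariance_of_ridge_predictions(small_session):
    """Full-rank PCA inputs give identical ridge predictions as raw data."""
    from synbmi import dimred

    sess, _, _ = small_session
    X = sess.neural
    Y = sess.velocity
    decomp = dimred.fit_pca(X, X.shape[1])
    Z = dimred.transform(decomp, X)
    lam = 1.0
    dx, t = build_history_design(X, lags=5)
    dz, _ = build_history_design(Z, lags=5)
    wx = fit_ridge(dx, Y[t], lam, lags=5)
    wz = fit_ridge(dz, Y[t], lam, lags=5)
    px, pz = dx @ wx.weights, dz @ wz.weights
    assert np.allclose(px, pz, atol=1e-6)
    cc = pearson_cc(px, pz)
    assert np.all(cc > 1 - 1e-6)


def test_ridge_matches_sklearn_oracle():
    """Penalized solve agrees with an independent ridge implementation."""
    sklearn_lm = pytest.importorskip("sklearn.linear_model")
    rng = np.random.default_rng(12)
    X = rng.normal(size=(100, 6))
    Y = rng.normal(size=(100, 2))
    lam = 3.0
    design = np.column_stack([np.ones(100), X])
    ours = fit_ridge(design, Y, lam, lags=1)
    ref = sklearn_lm.Ridge(alpha=lam, fit_intercept=True).fit(X, Y)
    assert np.allclose(ours.weights[1:], ref.coef_.T, atol=1e-8)
    assert np.allclose(ours.weights[0], ref.intercept_, atol=1e-8)
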