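"""PCA/NMF/dPCA against independent oracles, plus the VAF machinery."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles

from synbmi import dimred
from synbmi.dimred import (components_for_vaf, fit_dpca, fit_nmf, fit_pca,
                           marginalize_trials, reconstruct, transform, vaf)
from synbmi.session import BinnedSession, TrialTable


class TestVaf:
    def test_perfect_reconstruction(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        assert vaf(X, X) == pytest.approx(1.0)

    def test_column_means_give_zero(self):
        X = np.random.default_rng(0).normal(size=(10, 4))
        Xhat = np.tile(X.mean(axis=0), (10, 1))
        assert vaf(X, Xhat) == pytest.approx(0.0)

    def test_hand_worked_2x2(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        Xhat = np.full((2, 2), 0.5)
        assert vaf(X, Xhat) == pytest.approx(0.0)

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            vaf(np.ones((5, 2)), np.ones((5, 2)))


class TestPca:
    def test_exact_rank_one(self):
        X = np.outer(np.arange(1.0, 6.0), [1.0, 2.0, 3.0])
        d = fit_pca(X, 1)
        assert d.vaf_curve[0] == pytest.approx(1.0)

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 4))
        d = fit_pca(X, 4)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        for k in range(4):
            dot = abs(d.decoder[k] @ evecs[:, k])
            assert dot == pytest.approx(1.0, abs=1e-8)
        assert np.allclose(d.vaf_curve, np.cumsum(evals) / evals.sum(),
                           atol=1e-8)

    def test_full_rank_residual_negligible(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 5))
        d = fit_pca(X, 5)
        Xhat = reconstruct(d, d.activations)
        assert np.linalg.norm(X - Xhat) < 1e-8

    def test_decoder_rows_orthonormal(self):
        d = fit_pca(np.random.default_rng(5).normal(size=(30, 6)), 4)
        G = d.decoder @ d.decoder.T
        assert np.allclose(G, np.eye(4), atol=1e-8)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.zeros((5, 3)) + np.arange(3), 4)


class TestNmf:
    def test_exact_nonnegative_rank_one(self):
        X = np.outer([1.0, 2.0], [1.0, 0.0, 1.0])
        d = fit_nmf(X, 1, seed=0, compute_curve=False)
        rel = np.linalg.norm(X - d.activations @ d.weights) / np.linalg.norm(X)
        assert rel < 1e-6

    @pytest.mark.parametrize("init", ["nndsvda", "random"])
    @pytest.mark.parametrize("seed", range(5))
    def test_loss_monotone_nonincreasing(self, seed, init):
        rng = np.random.default_rng(seed)
        X = rng.uniform(size=(20, 6))
        d = fit_nmf(X, 3, seed=seed, n_restarts=1, init=init,
                    compute_curve=False)
        trace = np.array(d.fit_metadata["loss_trace"])
        assert np.all(np.diff(trace) <= 1e-10 * trace[0])

    def test_negative_input_rejected_with_channel(self):
        X = np.ones((4, 3))
        X[2, 1] = -0.1
        with pytest.raises(ValueError, match="channel 1"):
            fit_nmf(X, 2)

    def test_factors_nonnegative(self):
        X = np.random.default_rng(9).uniform(size=(15, 5))
        d = fit_nmf(X, 2, seed=1, compute_curve=False)
        assert d.weights.min() >= 0 and d.activations.min() >= 0


def _toy_session(offsets=None, n_reps=2, nb=6, n_channels=3, noise=0.0,
                 seed=0):
    """All 9 targets, n_reps trials each, optional per-target offsets."""
    rng = np.random.default_rng(seed)
    targets = np.tile(np.arange(1, 10), n_reps)
    n_trials = targets.size
    starts = np.arange(n_trials) * nb
    base = np.sin(np.linspace(0, np.pi, nb))[:, None] * np.ones(n_channels)
    rows = []
    for k in targets:
        block = base.copy()
        if offsets is not None:
            block = block + offsets[k - 1]
        rows.append(block + noise * rng.normal(size=block.shape))
    X = np.concatenate(rows)
    trials = TrialTable(
        start_bin=starts, end_bin=starts + nb, target=targets,
        context=np.array(["normal"] * n_trials, dtype=object),
        artifact_start=starts, artifact_end=starts,
    )
    return BinnedSession(neural=X, emg=np.zeros((X.shape[0], 2)),
                         kinematics=np.zeros((X.shape[0], 4)),
                         trials=trials, bin_width=0.02)


class TestMarginalization:
    def test_identity_holds_exactly(self):
        offs = np.random.default_rng(1).normal(size=(9, 3))
        sess = _toy_session(offsets=offs, noise=0.3, seed=2)
        m = marginalize_trials(sess, aligned_len=6)
        recon = (m.grand_mean + m.marginals["time"] + m.marginals["target"] +
                 m.residual)
        assert np.allclose(recon, m.aligned, atol=1e-12)

    def test_identical_trials_have_zero_target_marginal(self):
        sess = _toy_session(offsets=None)
        m = marginalize_trials(sess, aligned_len=6)
        assert np.allclose(m.marginals["target"], 0.0, atol=1e-12)

    def test_per_target_offsets_recovered(self):
        offs = np.zeros((9, 3))
        offs[:, 0] = np.arange(9, dtype=float)
        sess = _toy_session(offsets=offs)
        m = marginalize_trials(sess, aligned_len=6)
        expected = offs - offs.mean(axis=0)
        for i, k in enumerate(sess.trials.target):
            block = m.marginals["target"][i * 6:(i + 1) * 6]
            assert np.allclose(block, expected[k - 1], atol=1e-12)

    def test_missing_target_class_rejected(self):
        sess = _toy_session()
        keep = sess.trials.target != 4
        sub = sess.replace(trials=sess.trials.subset(np.flatnonzero(keep)))
        with pytest.raises(ValueError, match=r"\[4\]"):
            marginalize_trials(sub, aligned_len=6)


class TestDpca:
    def test_rank_two_target_structure_recovered(self):
        rng = np.random.default_rng(6)
        offs = rng.normal(size=(9, 2)) @ rng.normal(size=(2, 6))
        sess = _toy_session(offsets=offs, n_channels=6)
        m = marginalize_trials(sess, aligned_len=6)
        d = fit_dpca(m.aligned, m.marginals, 2)
        axes = d.fit_metadata["axes"]["target"]
        pred = ((m.aligned - m.aligned.mean(0)) @ axes["decoder"].T
                @ axes["encoder"].T)
        assert vaf(m.marginals["target"], pred, centered=False) >= 0.999

    def test_no_target_structure_explains_nothing(self):
        sess = _toy_session(offsets=None, noise=0.05, seed=3, n_channels=4)
        m = marginalize_trials(sess, aligned_len=6)
        d = fit_dpca(m.aligned, m.marginals, 2)
        expl = d.fit_metadata["axes"]["target"]["explained_marginal_variance"]
        # target marginal is pure averaging noise; nothing real to explain
        assert np.all(np.abs(expl) < 0.5)

    def test_single_full_marginalization_equals_pca(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 6)) @ rng.normal(size=(6, 6))
        Xc = X - X.mean(axis=0)
        dp = fit_dpca(X, {"all": Xc}, 3, ridge_mu=0.0,
                      activation_param="all")
        pc = fit_pca(X, 3)
        angles = subspace_angles(dp.decoder.T, pc.decoder.T)
        assert angles.max() < 1e-6

    def test_singular_gram_with_zero_mu_rejected(self):
        X = np.zeros((10, 3))
        X[:, 0] = np.arange(10.0)
        X[:, 1] = 2 * X[:, 0]          # exactly collinear
        with pytest.raises(np.linalg.LinAlgError, match="ridge_mu"):
            fit_dpca(X, {"all": X - X.mean(0)}, 2, ridge_mu=0.0,
                     activation_param="all")


class TestTransformReconstruct:
    def test_pca_full_rank_round_trip(self):
        X = np.random.default_rng(2).normal(size=(12, 4))
        d = fit_pca(X, 4)
        assert np.allclose(reconstruct(d, transform(d, X)), X, atol=1e-8)

    def test_nmf_transform_of_weight_row_is_one_hot(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0.1, 1.0, size=(30, 5))
        d = fit_nmf(X, 2, seed=2, compute_curve=False)
        H = transform(d, d.weights[0:1] * 3.0)
        # NNLS against W: a scaled pure synergy maps to that synergy alone
        assert H[0, 0] == pytest.approx(3.0, rel=1e-6)
        assert abs(H[0, 1]) < 1e-8

    def test_channel_mismatch_rejected(self):
        d = fit_pca(np.random.default_rng(1).normal(size=(10, 4)), 2)
        with pytest.raises(ValueError, match="channel"):
            transform(d, np.zeros((5, 3)))


class TestComponentsForVaf:
    def test_pca_vaf_counts_on_synthetic_rank(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 3)) @ rng.normal(size=(3, 8))
        # exactly rank 3: two components cannot reach a 0.999 threshold,
        # three reach VAF 1
        assert components_for_vaf(X, "pca", 0.999) == 3

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            components_for_vaf(np.random.default_rng(0).normal(size=(10, 3)),
                               "pca", threshold=1.5)


class TestExternalOracles:
    """Cross-checks against an independent library implementation."""

    def test_pca_subspace_matches_sklearn(self):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        rng = np.random.default_rng(10)
        X = rng.normal(size=(80, 6))
        ours = fit_pca(X, 4)
        ref = sklearn_pca(n_components=4).fit(X)
        for k in range(4):
            assert abs(ours.decoder[k] @ ref.components_[k]) == \
                pytest.approx(1.0, abs=1e-8)
        assert np.allclose(ours.vaf_curve,
                           np.cumsum(ref.explained_variance_ratio_),
                           atol=1e-8)

    def test_nmf_loss_competitive_with_sklearn(self):
        sklearn_nmf = pytest.importorskip("sklearn.decomposition").NMF
        rng = np.random.default_rng(11)
        X = rng.uniform(0.0, 1.0, size=(60, 8))
        ours = fit_nmf(X, 3, seed=0, max_iter=2000, tol=1e-10,
                       compute_curve=False)
        ref = sklearn_nmf(n_components=3, init="nndsvda", max_iter=2000,
                          tol=1e-10).fit(X)
        loss_ours = np.sum((X - ours.activations @ ours.weights) ** 2)
        loss_ref = ref.reconstruction_err_ ** 2
        assert loss_ours <= 1.05 * loss_ref
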