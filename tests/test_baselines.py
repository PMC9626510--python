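import numpy as np
import pytest
from scipy import optimize, stats

from arp300.baselines import (BaselineScorer, fit_baseline, fit_blda, fit_lda,
                              fit_svm_linear, fit_swlda)


def _two_gaussians(rng, n=60, d=2, sep=6.0):
    X0 = rng.standard_normal((n, d))
    X1 = rng.standard_normal((n, d)) + sep / np.sqrt(d)
    X = np.vstack([X0, X1])
    y = np.r_[np.zeros(n), np.ones(n)].astype(int)
    return X, y


class TestLDA:
    def test_separable_clouds_zero_training_errors(self, rng):
        X, y = _two_gaussians(rng)
        s = fit_lda(X, y)
        pred = (s.score(X) > 0).astype(int)
        assert (pred == y).all()

    def test_no_signal_small_weights(self, rng):
        X = rng.standard_normal((400, 5))
        y = np.r_[np.zeros(200), np.ones(200)].astype(int)
        s = fit_lda(X, y)
        # weight norm tiny relative to a separated problem on the same scale
        Xs, ys = _two_gaussians(rng, n=200, d=5)
        assert np.linalg.norm(s.weights) < 0.1 * np.linalg.norm(fit_lda(Xs, ys).weights)

    def test_duplication_invariance(self, rng):
        X, y = _two_gaussians(rng, n=40, d=4)
        a = fit_lda(X, y, shrinkage=0.1)
        b = fit_lda(np.vstack([X, X]), np.r_[y, y], shrinkage=0.1)
        cos = a.weights @ b.weights / (np.linalg.norm(a.weights) * np.linalg.norm(b.weights))
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_matches_direct_solve_small_d(self, rng):
        """Woodbury/Gram path vs forming the d x d shrunk covariance."""
        X, y = _two_gaussians(rng, n=30, d=8, sep=2.0)
        a = 0.3
        s = fit_lda(X, y, shrinkage=a)
        mu0, mu1 = X[y == 0].mean(0), X[y == 1].mean(0)
        Xc = X.copy()
        Xc[y == 0] -= mu0
        Xc[y == 1] -= mu1
        S = Xc.T @ Xc / len(X)
        mu = np.trace(S) / 8
        w_ref = np.linalg.solve((1 - a) * S + a * mu * np.eye(8), mu1 - mu0)
        assert np.allclose(s.weights, w_ref, rtol=1e-8, atol=1e-10)

    def test_wide_data_handled(self, rng):
        # d >> n must stay tractable (no d x d matrix is ever formed)
        X = rng.standard_normal((50, 6000))
        y = np.r_[np.zeros(25), np.ones(25)].astype(int)
        X[y == 1, :10] += 2.0
        s = fit_lda(X, y)
        assert (s.score(X[y == 1]).mean() > s.score(X[y == 0]).mean())

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_lda(rng.standard_normal((10, 3)), np.ones(10, dtype=int))


class TestBLDA:
    def test_prior_free_limit_equals_ols(self, rng):
        X = rng.standard_normal((500, 20))
        w_true = rng.standard_normal(20)
        y = ((X @ w_true + 0.1 * rng.standard_normal(500)) > 0).astype(int)
        s = fit_blda(X, y, fixed_alpha=1e-10, fixed_beta=1.0)
        t = np.where(y == 1, 1.0, -1.0)
        Xc = X - X.mean(0)
        w_ols, *_ = np.linalg.lstsq(Xc, t - t.mean(), rcond=None)
        assert np.abs(s.weights - w_ols).max() < 1e-6

    def test_weight_recovery_correlation(self, rng):
        n, d = 500, 20
        X = rng.standard_normal((n, d))
        w_true = rng.standard_normal(d)
        z = X @ w_true + 0.5 * rng.standard_normal(n)
        y = (z > np.median(z)).astype(int)
        s = fit_blda(X, y)
        corr = np.corrcoef(s.weights, w_true)[0, 1]
        assert corr >= 0.99

    def test_evidence_nondecreasing(self, rng):
        X = rng.standard_normal((200, 30))
        w_true = rng.standard_normal(30)
        y = ((X @ w_true + rng.standard_normal(200)) > 0).astype(int)
        s = fit_blda(X, y)
        ev = np.asarray(s.evidence)
        assert len(ev) >= 2
        assert (np.diff(ev) >= -1e-6 * np.abs(ev[:-1])).all()

    def test_dual_path_matches_primal(self, rng):
        # same problem solved with n > d (primal) and padded to d > n (dual)
        X = rng.standard_normal((60, 10))
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        X[y == 1, 0] += 1.5
        wp = fit_blda(X, y, fixed_alpha=2.0, fixed_beta=3.0).weights
        Xwide = np.hstack([X, np.zeros((60, 70))])  # dual branch, same problem
        wd = fit_blda(Xwide, y, fixed_alpha=2.0, fixed_beta=3.0).weights
        assert np.allclose(wp, wd[:10], atol=1e-8)
        assert np.abs(wd[10:]).max() < 1e-8

    def test_nonconvergence_flagged(self, rng):
        X = rng.standard_normal((50, 5))
        y = np.r_[np.zeros(25), np.ones(25)].astype(int)
        X[y == 1, 0] += 1.0
        with pytest.warns(RuntimeWarning, match="did not converge"):
            s = fit_blda(X, y, tol=1e-300, max_iter=3)
        assert not s.converged
        assert s.n_iter == 3

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_blda(rng.standard_normal((10, 3)), np.zeros(10, dtype=int))


class TestSWLDA:
    def test_single_informative_feature_selected_first(self, rng):
        n, d = 200, 10
        X = rng.standard_normal((n, d))
        y = (X[:, 3] + 0.2 * rng.standard_normal(n) > 0).astype(int)
        s = fit_swlda(X, y)
        assert s.hyper["selected"][0] == 3
        assert s.weights[3] != 0

    def test_p_enter_zero_empty_model(self, rng):
        X, y = _two_gaussians(rng, n=50, d=5)
        s = fit_swlda(X, y, p_enter=0.0)
        assert s.n_active_features == 0
        assert np.ptp(s.score(X)) == 0.0  # constant score

    def test_step_cap_limits_features(self, rng):
        n, d = 300, 500
        X = rng.standard_normal((n, d))
        y = (X[:, :50].sum(axis=1) + 0.1 * rng.standard_normal(n) > 0).astype(int)
        s = fit_swlda(X, y, p_enter=0.5, p_remove=0.99, max_steps=60)
        assert 0 < s.n_active_features <= 60

    def test_max_steps_positive(self, rng):
        X, y = _two_gaussians(rng)
        with pytest.raises(ValueError):
            fit_swlda(X, y, max_steps=0)

    def test_backward_removal_happens(self, rng):
        # feature 0 = feature 1 + tiny noise: once a better feature enters,
        # a redundant one must be removable without error
        n = 300
        base = rng.standard_normal(n)
        X = np.column_stack([
            base + 0.5 * rng.standard_normal(n),
            base + 0.5 * rng.standard_normal(n),
            rng.standard_normal(n),
        ])
        y = (base > 0).astype(int)
        s = fit_swlda(X, y, p_enter=0.3, p_remove=0.05, max_steps=10)
        assert s.n_active_features <= 2

    def test_separates_toy_data(self, rng):
        X, y = _two_gaussians(rng, n=80, d=6)
        s = fit_swlda(X, y)
        auc_pos = s.score(X[y == 1]).mean()
        auc_neg = s.score(X[y == 0]).mean()
        assert auc_pos > auc_neg


class TestSVM:
    def test_separable_perfect_training_accuracy(self, rng):
        X = np.vstack([0.2 * rng.standard_normal((40, 3)) - 5.0,
                       0.2 * rng.standard_normal((40, 3)) + 5.0])
        y = np.r_[np.zeros(40), np.ones(40)].astype(int)
        s = fit_svm_linear(X, y)
        assert ((s.score(X) > 0).astype(int) == y).all()
        # zero hinge loss on a large-margin problem
        margins = np.where(y == 1, 1, -1) * s.score(X)
        assert (margins >= 1 - 1e-6).all()

    def test_small_C_shrinks_weights(self, rng):
        X, y = _two_gaussians(rng, n=40, d=3, sep=2.0)
        big = np.linalg.norm(fit_svm_linear(X, y, C=1.0).weights)
        small = np.linalg.norm(fit_svm_linear(X, y, C=1e-6).weights)
        assert small < 1e-3 * big

    def test_matches_dual_qp_oracle(self, rng):
        """sklearn decision values vs a generic box-constrained dual QP."""
        X, y = _two_gaussians(rng, n=10, d=2, sep=3.0)  # 20 points
        C = 1.0
        s = fit_svm_linear(X, y, C=C)
        t = np.where(y == 1, 1.0, -1.0)
        K = (X @ X.T) * np.outer(t, t)

        def neg_dual(a):
            return 0.5 * a @ K @ a - a.sum()

        def neg_dual_grad(a):
            return K @ a - np.ones_like(a)

        n = len(y)
        res = optimize.minimize(
            neg_dual, np.full(n, C / 2), jac=neg_dual_grad, method="SLSQP",
            bounds=[(0, C)] * n,
            constraints=[{"type": "eq", "fun": lambda a: a @ t,
                          "jac": lambda a: t}],
            options={"maxiter": 2000, "ftol": 1e-14},
        )
        assert res.success
        w = (res.x * t) @ X
        sv = (res.x > 1e-6) & (res.x < C - 1e-6)
        b = float(np.mean(t[sv] - X[sv] @ w))
        assert np.abs(s.score(X) - (X @ w + b)).max() < 1e-4

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_svm_linear(rng.standard_normal((10, 3)), np.zeros(10, dtype=int))

    def test_nonpositive_C_rejected(self, rng):
        X, y = _two_gaussians(rng)
        with pytest.raises(ValueError):
            fit_svm_linear(X, y, C=0.0)


class TestBaselineScorerContract:
    @pytest.mark.parametrize("method", ["lda", "blda", "swlda", "svm"])
    def test_fit_score_on_epochs(self, method, highsnr_epochs):
        idx = np.arange(highsnr_epochs.n_epochs)
        tr, te = idx[: 9 * 60], idx[9 * 60:]
        scorer = BaselineScorer(method).fit(highsnr_epochs.subset(tr))
        s = scorer.score(highsnr_epochs.subset(te))
        assert len(s) == len(te)
        labels = highsnr_epochs.labels[te]
        assert s[labels == 1].mean() > s[labels == 0].mean()

    def test_unknown_method_rejected(self, highsnr_epochs):
        with pytest.raises(ValueError, match="unknown method"):
            fit_baseline("mlp", highsnr_epochs)

    def test_unfitted_score_rejected(self, highsnr_epochs):
        with pytest.raises(RuntimeError):
            BaselineScorer("lda").score(highsnr_epochs)
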