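"""Classical linear scorers on flattened epoch vectors.

All four methods score a flattened 200 x 30 = 6,000-dimensional epoch with
an affine function; higher = more target-like.  Because the feature
dimension far exceeds the sample count, LDA and BLDA work in the Gram
(sample-space) representation throughout, which keeps fitting at
O(n^2 d + n^3) instead of O(d^3).

Printed hyper-parameters: SVM linear kernel with C = 1; SWLDA p-to-enter
0.1, p-to-remove 0.15, at most 60 steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .preprocess import EpochSet

__all__ = [
    "LinearScorer", "BaselineScorer", "fit_lda", "fit_blda", "fit_swlda",
    "fit_svm_linear", "fit_baseline", "BASELINE_METHODS",
]

BASELINE_METHODS = ("lda", "blda", "swlda", "svm")


@dataclass
class LinearScorer:
    """Affine scorer: score(x) = w . x + b."""

    weights: np.ndarray
    bias: float
    method: str
    hyper: dict = field(default_factory=dict)

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.weights):
            raise ValueError(
                f"expected {len(self.weights)} features, got {X.shape[1]}"
            )
        return X @ self.weights + self.bias

    @property
    def n_active_features(self) -> int:
        return int(np.count_nonzero(self.weights))


def _check_two_class(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).ravel()
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(
            f"need binary labels 0/1 with both classes present, got classes {classes}"
        )
    return y


# ---------------------------------------------------------------------------
# LDA with analytic (Ledoit-Wolf) shrinkage of the pooled covariance
# ---------------------------------------------------------------------------

def _ledoit_wolf_shrinkage(Xc: np.ndarray, G: np.ndarray) -> float:
    """Shrinkage intensity toward the scaled identity, computed from the
    Gram matrix only (never forms the d x d covariance)."""
    n, d = Xc.shape
    tr_S = np.trace(G) / n  # = trace of S
    mu = tr_S / d
    frob_S2 = float((G * G).sum()) / n**2  # ||S||_F^2
    d2 = frob_S2 - 2 * mu * tr_S + d * mu**2
    if d2 <= 0:
        return 0.0
    g_ii = np.einsum("ii->i", G)
    g2_ii = np.einsum("ij,ji->i", G, G)
    # sum_i ||x_i x_i^T - S||_F^2 = sum_i ||x_i||^4 - 2 x_i^T S x_i + ||S||^2
    b_sum = float((g_ii**2).sum() - 2.0 / n * g2_ii.sum() + n * frob_S2)
    b2 = min(b_sum / n**2, d2)
    return float(np.clip(b2 / d2, 0.0, 1.0))


def fit_lda(X: np.ndarray, y: np.ndarray, shrinkage: float | None = None) -> LinearScorer:
    """Fisher discriminant with a shrinkage-regularised pooled covariance.

    ``shrinkage=None`` selects the analytic Ledoit-Wolf intensity.  The
    linear system is solved through the Woodbury identity on the n x n Gram
    matrix, so d may be large.
    """
    X = np.asarray(X, dtype=float)
    y = _check_two_class(y)
    n, d = X.shape
    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    Xc = X.copy()
    Xc[y == 0] -= mu0
    Xc[y == 1] -= mu1
    G = Xc @ Xc.T
    a = _ledoit_wolf_shrinkage(Xc, G) if shrinkage is None else float(shrinkage)
    if not 0.0 <= a <= 1.0:
        raise ValueError("shrinkage must be in [0, 1]")
    mu = np.trace(G) / n / d  # mean eigenvalue of pooled covariance
    mu = max(mu, np.finfo(float).tiny)
    delta = mu1 - mu0
    if a >= 1.0:
        w = delta / mu
    else:
        # (a mu I + (1-a)/n Xc^T Xc)^{-1} delta via Woodbury
        am = a * mu if a > 0 else 1e-12 * mu  # keep the system well-posed
        inner = (n / (1.0 - a) * am) * np.eye(n) + G
        v = np.linalg.solve(inner, Xc @ delta)
        w = (delta - Xc.T @ v) / am
    b = -float(w @ (mu0 + mu1)) / 2.0
    return LinearScorer(w, b, "lda", {"shrinkage": a})


# ---------------------------------------------------------------------------
# Bayesian LDA: linear regression on +-1 labels, evidence-maximised
# hyper-parameters (isotropic Gaussian prior on weights, bias unpenalised)
# ---------------------------------------------------------------------------

@dataclass
class BLDAResult(LinearScorer):
    alpha: float = np.nan
    beta: float = np.nan
    converged: bool = True
    n_iter: int = 0
    evidence: list[float] = field(default_factory=list)


def fit_blda(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 100,
    fixed_alpha: float | None = None,
    fixed_beta: float | None = None,
) -> BLDAResult:
    """Bayesian linear regression of coded labels (+1 target / -1 non-target).

    The weight prior is zero-mean isotropic Gaussian with precision alpha
    (bias excluded via centring); noise precision is beta.  Both are updated
    by evidence maximisation until the relative change drops below ``tol``.
    Non-convergence is flagged on the result and warned about, never silent.
    """
    X = np.asarray(X, dtype=float)
    y = _check_two_class(y)
    t = np.where(y == 1, 1.0, -1.0)
    n, d = X.shape
    x_mean = X.mean(axis=0)
    t_mean = t.mean()
    Xc = X - x_mean
    tc = t - t_mean

    # eigenbasis of the data curvature; dual (Gram) when d > n
    if d <= n:
        lam, V = np.linalg.eigh(Xc.T @ Xc)  # (d,)
        lam = np.clip(lam, 0.0, None)
        proj = V.T @ (Xc.T @ tc)  # coords of X^T t in eigenbasis

        def weights(alpha, beta):
            return V @ (proj / (lam + alpha / beta))
        lam_full = lam
        r = d
    else:
        G = Xc @ Xc.T
        lam, U = np.linalg.eigh(G)
        lam = np.clip(lam, 0.0, None)
        uy = U.T @ tc

        def weights(alpha, beta):
            coef = uy / (lam + alpha / beta)
            return Xc.T @ (U @ coef)
        lam_full = lam
        r = n

    alpha = 1.0 if fixed_alpha is None else float(fixed_alpha)
    beta = 1.0 if fixed_beta is None else float(fixed_beta)
    evidence = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = weights(alpha, beta)
        fit_vec = Xc @ w
        rss = float(((tc - fit_vec) ** 2).sum())
        wnorm2 = float(w @ w)
        gamma = float(np.sum(beta * lam_full / (beta * lam_full + alpha)))
        # log marginal likelihood (up to constants in n)
        logdet = float(np.sum(np.log(alpha + beta * lam_full))) + (d - r) * np.log(alpha)
        ev = 0.5 * (
            d * np.log(alpha) + n * np.log(beta)
            - beta * rss - alpha * wnorm2 - logdet - n * np.log(2 * np.pi)
        )
        evidence.append(ev)
        new_alpha = alpha if fixed_alpha is not None else gamma / max(wnorm2, 1e-300)
        new_beta = beta if fixed_beta is not None else max(n - gamma, 1e-12) / max(rss, 1e-300)
        rel = max(
            abs(new_alpha - alpha) / max(abs(alpha), 1e-300),
            abs(new_beta - beta) / max(abs(beta), 1e-300),
        )
        alpha, beta = new_alpha, new_beta
        if rel < tol:
            converged = True
            break
    if not converged and (fixed_alpha is None or fixed_beta is None):
        warnings.warn(
            f"BLDA evidence maximisation did not converge in {max_iter} iterations",
            RuntimeWarning,
        )
    w = weights(alpha, beta)
    b = float(t_mean - x_mean @ w)
    return BLDAResult(
        weights=w, bias=b, method="blda",
        hyper={"tol": tol, "max_iter": max_iter},
        alpha=alpha, beta=beta, converged=converged, n_iter=it,
        evidence=evidence,
    )


# ---------------------------------------------------------------------------
# Stepwise regression (SWLDA): forward entry by partial-F p-value,
# backward removal, capped step count
# ---------------------------------------------------------------------------

def fit_swlda(
    X: np.ndarray,
    y: np.ndarray,
    p_enter: float = 0.1,
    p_remove: float = 0.15,
    max_steps: int = 60,
) -> LinearScorer:
    """Forward-backward stepwise OLS on +-1 coded labels.

    Each step adds the candidate with the smallest partial-F p-value if it is
    below ``p_enter`` (ties broken by lowest feature index), then removes any
    active feature whose p-value exceeds ``p_remove``.  Stops when nothing
    changes or after ``max_steps`` steps, so at most ``max_steps`` features
    are ever active.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    X = np.asarray(X, dtype=float)
    y = _check_two_class(y)
    t = np.where(y == 1, 1.0, -1.0)
    n, d = X.shape

    active: list[int] = []
    # residualised candidates and response (intercept projected out up front)
    Z = X - X.mean(axis=0)
    r = t - t.mean()
    znorm2 = np.einsum("ij,ij->j", Z, Z)
    eps = 1e-10 * max(znorm2.max(), 1.0)

    def ols_pvalues(cols: list[int]):
        A = np.column_stack([np.ones(n)] + [X[:, j] for j in cols])
        coef, _, _, _ = np.linalg.lstsq(A, t, rcond=None)
        resid = t - A @ coef
        dof = n - A.shape[1]
        if dof <= 0:
            return coef, np.zeros(len(cols))
        s2 = float(resid @ resid) / dof
        XtX_inv = np.linalg.pinv(A.T @ A)
        se = np.sqrt(np.clip(s2 * np.diag(XtX_inv), 1e-300, None))
        tstat = coef / se
        p = 2.0 * stats.t.sf(np.abs(tstat), dof)
        return coef, p[1:]  # drop intercept

    for _ in range(max_steps):
        changed = False
        # --- forward: partial F of each excluded candidate
        k = len(active)
        dof = n - k - 2  # intercept + active + candidate
        if dof > 0:
            rss = float(r @ r)
            with np.errstate(divide="ignore", invalid="ignore"):
                c = Z.T @ r
                gain = np.where(znorm2 > eps, c**2 / np.where(znorm2 > eps, znorm2, 1.0), 0.0)
                s2 = (rss - gain) / dof
                F = np.where(s2 > 0, gain / np.where(s2 > 0, s2, 1.0), np.inf)
            F[active] = -np.inf
            F[znorm2 <= eps] = -np.inf
            pvals = stats.f.sf(F, 1, dof)
            best = int(np.argmin(pvals))  # argmin takes the lowest index on ties
            if np.isfinite(F[best]) and pvals[best] < p_enter:
                active.append(best)
                q = Z[:, best] / np.sqrt(znorm2[best])
                r = r - q * (q @ r)
                Z = Z - np.outer(q, q @ Z)
                znorm2 = np.einsum("ij,ij->j", Z, Z)
                changed = True
        # --- backward: drop the worst active feature if above p_remove
        if active:
            _, p_act = ols_pvalues(active)
            worst = int(np.argmax(p_act))
            if p_act[worst] > p_remove:
                removed = active.pop(worst)
                # rebuild the residualised space from scratch (cheap: <= 60 cols)
                Z = X - X.mean(axis=0)
                r = t - t.mean()
                for j in active:
                    nj = float(Z[:, j] @ Z[:, j])
                    if nj <= eps:
                        continue
                    q = Z[:, j] / np.sqrt(nj)
                    r = r - q * (q @ r)
                    Z = Z - np.outer(q, q @ Z)
                znorm2 = np.einsum("ij,ij->j", Z, Z)
                changed = changed or removed is not None
        if not changed:
            break

    w = np.zeros(d)
    if active:
        coef, _ = ols_pvalues(active)
        b = float(coef[0])
        for j, cj in zip(active, coef[1:]):
            w[j] = cj
    else:
        b = float(t.mean())
    return LinearScorer(w, b, "swlda", {
        "p_enter": p_enter, "p_remove": p_remove, "max_steps": max_steps,
        "selected": list(active),  # insertion order
    })


# ---------------------------------------------------------------------------
# Linear SVM (delegated to libsvm via scikit-learn; not a contribution here)
# ---------------------------------------------------------------------------

def fit_svm_linear(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> LinearScorer:
    """Soft-margin linear SVM; score = signed decision value."""
    from sklearn.svm import SVC

    X = np.asarray(X, dtype=float)
    y = _check_two_class(y)
    if C <= 0:
        raise ValueError("C must be positive")
    clf = SVC(kernel="linear", C=C, tol=1e-7)
    clf.fit(X, y)
    w = np.asarray(clf.coef_).ravel()
    b = float(clf.intercept_[0])
    return LinearScorer(w, b, "svm", {"C": C})


# ---------------------------------------------------------------------------
# EpochSet adapter: flatten + per-feature z-scoring fitted on training data
# ---------------------------------------------------------------------------

_FITTERS = {
    "lda": fit_lda,
    "blda": fit_blda,
    "swlda": fit_swlda,
    "svm": fit_svm_linear,
}


@dataclass
class BaselineScorer:
    """TrainedScorer wrapper: flattens epochs, z-scores features (train-fold
    statistics only), then applies a fitted linear scorer."""

    method: str
    hyper: dict = field(default_factory=dict)
    linear: LinearScorer | None = None
    _mean: np.ndarray | None = None
    _std: np.ndarray | None = None

    def fit(self, epochs: EpochSet) -> "BaselineScorer":
        X = epochs.tensor.reshape(epochs.n_epochs, -1).astype(float)
        self._mean = X.mean(axis=0)
        std = X.std(axis=0)
        self._std = np.where(std > 0, std, 1.0)
        Xz = (X - self._mean) / self._std
        self.linear = _FITTERS[self.method](Xz, epochs.labels, **self.hyper)
        return self

    def score(self, epochs: EpochSet) -> np.ndarray:
        if self.linear is None:
            raise RuntimeError("scorer not fitted")
        X = epochs.tensor.reshape(epochs.n_epochs, -1).astype(float)
        Xz = (X - self._mean) / self._std
        return self.linear.score(Xz)


def fit_baseline(method: str, epochs: EpochSet, **hyper) -> BaselineScorer:
    if method not in _FITTERS:
        raise ValueError(f"unknown method {method!r}; choose from {BASELINE_METHODS}")
    return BaselineScorer(method, hyper).fit(epochs)
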