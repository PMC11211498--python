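"""Missing-psi handling: probabilistic-PCA imputation and sentinel filling.

Coverage-failed psi entries are missing not at random in real data, but the
cells x events matrix is well approximated by a low-rank model because
splicing profiles covary within cell types.  `bpca_impute` fits a
probabilistic PCA model

    y_i = W x_i + mu + eps,   x_i ~ N(0, I_q),   eps ~ N(0, sigma^2 I)

by expectation-maximization over the observed entries only (Ilin & Raiko
style updates), then replaces each missing entry by its conditional mean
``mu + W E[x]`` under the fitted model.  Observed entries are never altered;
imputed values are clipped to [0, 1].  This is the isotropic-noise member of
the Bayesian-PCA family; it shares the latent-factor imputation mechanism
while avoiding per-component relevance hyperpriors.

`sentinel_fill` is the alternative "flag" mode: missing entries are replaced
by a constant far outside [0, 1] so that downstream distance computations
treat missingness as its own state.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io import PsiMatrix, ValidationError

__all__ = ["bpca_impute", "sentinel_fill", "ppca_em"]


def _as_matrix(psi):
    if isinstance(psi, PsiMatrix):
        return psi.psi.copy(), psi.observed.copy()
    arr = np.asarray(psi, dtype=float)
    return arr.copy(), ~np.isnan(arr)


def ppca_em(Y: np.ndarray, observed: np.ndarray, n_components: int,
            tol: float = 1e-4, max_iter: int = 200, seed: int = 0):
    """EM for probabilistic PCA with missing entries.

    Parameters are the cells x events data matrix ``Y`` (entries where
    ``observed`` is False are ignored), the latent dimensionality, the
    relative log-likelihood convergence tolerance and the iteration cap.

    Returns ``(mu, W, sigma2, X, ll)`` where ``X`` holds per-row posterior
    mean latent scores and ``ll`` the final observed-data log-likelihood.
    """
    n, d = Y.shape
    q = n_components
    rng = np.random.default_rng(seed)

    mu = np.array([Y[observed[:, j], j].mean() for j in range(d)])
    resid = np.where(observed, Y - mu, 0.0)
    sigma2 = max(resid[observed].var(), 1e-6)
    W = rng.normal(scale=np.sqrt(sigma2), size=(d, q))

    obs_idx = [np.flatnonzero(observed[i]) for i in range(n)]
    obs_f = observed.astype(float)
    n_obs_col = observed.sum(axis=0)
    n_obs_total = observed.sum()
    eye_q = np.eye(q)
    ll_old = -np.inf
    X = np.zeros((n, q))
    for iteration in range(max_iter):
        # E-step: per-row posterior over latent scores, plus the observed-data
        # log-likelihood via the matrix determinant lemma / Woodbury identity
        M = np.zeros((n, q))            # posterior means of x_i
        Cov = np.zeros((n, q, q))       # posterior covariances
        ll = 0.0
        for i in range(n):
            o = obs_idx[i]
            Wo = W[o]
            r = Y[i, o] - mu[o]
            WtW = Wo.T @ Wo
            A = np.linalg.inv(sigma2 * eye_q + WtW)
            rhs = Wo.T @ r
            m = A @ rhs
            M[i] = m
            Cov[i] = sigma2 * A
            _, logdet_inner = np.linalg.slogdet(eye_q + WtW / sigma2)
            quad = (r @ r - rhs @ A @ rhs) / sigma2
            ll -= 0.5 * (o.size * np.log(2 * np.pi * sigma2)
                         + logdet_inner + quad)
        Sxx = Cov + M[:, :, None] * M[:, None, :]   # E[x x^T] per row
        # M-step (all features at once)
        pred = M @ W.T
        mu_new = np.where(observed, Y - pred, 0.0).sum(axis=0) / n_obs_col
        G = np.einsum("ij,iqp->jqp", obs_f, Sxx, optimize=True)  # d x q x q
        B = (np.where(observed, Y - mu_new, 0.0)).T @ M
        W_new = np.linalg.solve(G + 1e-12 * eye_q, B[:, :, None])[:, :, 0]
        # noise variance over observed entries
        resid = np.where(observed, Y - mu_new - M @ W_new.T, 0.0)
        cov_term = np.einsum("dq,iqp,dp,id->", W_new, Cov, W_new, obs_f,
                             optimize=True)
        sigma2 = max(((resid ** 2).sum() + cov_term) / n_obs_total, 1e-10)
        mu, W = mu_new, W_new
        X = M
        if np.isfinite(ll_old) and abs(ll - ll_old) < tol * abs(ll_old):
            break
        ll_old = ll
    else:
        warnings.warn(f"PPCA EM did not converge in {max_iter} iterations; "
                      "returning best iterate")
    return mu, W, sigma2, X, ll


def bpca_impute(psi, n_components: int = 10, tol: float = 1e-4,
                max_iter: int = 200, seed: int = 0) -> np.ndarray:
    """Impute missing psi entries from a probabilistic PCA fit.

    Accepts a :class:`~isletsplice.io.PsiMatrix` or a NaN-masked array and
    returns a complete cells x events array.  Observed entries are returned
    bit-identical; imputed entries are the model's conditional means clipped
    to [0, 1].
    """
    Y, observed = _as_matrix(psi)
    n, d = Y.shape
    if observed.all():
        return Y
    if (~observed).all(axis=0).any():
        raise ValidationError("event with all entries missing cannot be imputed")
    if (~observed).all(axis=1).any():
        raise ValidationError("cell with all entries missing cannot be imputed")
    if (observed.sum(axis=0) < 2).any():
        raise ValidationError("each event must be observed in >= 2 cells")
    if n_components >= min(n, d):
        raise ValidationError(
            f"n_components={n_components} must be < min(cells, events)={min(n, d)}")
    mu, W, sigma2, X, _ = ppca_em(Y, observed, n_components, tol=tol,
                                  max_iter=max_iter, seed=seed)
    filled = Y.copy()
    miss_rows, miss_cols = np.nonzero(~observed)
    filled[miss_rows, miss_cols] = np.clip(
        mu[miss_cols] + np.einsum("ij,ij->i", W[miss_cols], X[miss_rows]),
        0.0, 1.0)
    return filled


def sentinel_fill(psi, sentinel: float = -1.0) -> np.ndarray:
    """Replace missing entries by a constant sentinel outside [0, 1]."""
    if 0.0 <= sentinel <= 1.0:
        raise ValidationError("sentinel must lie outside [0, 1]")
    Y, observed = _as_matrix(psi)
    Y[~observed] = sentinel
    return Y
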