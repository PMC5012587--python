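"""Two-component Gaussian mixture with a single shared covariance (EEE).

The "EEE" constraint (equal volume, shape and orientation) means both
components share one covariance matrix; only the means and mixing weights
differ.  Fitted by expectation-maximization with a k-means-style
initialization.  Used to separate "better compensated" from "modestly
compensated" genes across genetic backgrounds.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import logsumexp


class GaussianMixtureEEE:
    """EM fit of a k-component Gaussian mixture with shared covariance.

    Parameters
    ----------
    n_components : number of components (default 2).
    tol : absolute log-likelihood gain below which EM stops.
    max_iter : iteration cap; non-convergence keeps the best state and sets
        ``converged_ = False``.
    ridge : diagonal regularization added when the pooled covariance is
        singular (applied with a warning).
    """

    def __init__(self, n_components: int = 2, tol: float = 1e-8,
                 max_iter: int = 500, ridge: float = 1e-8,
                 random_state: int | None = 0):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.ridge = ridge
        self.random_state = random_state

    # -- internals -----------------------------------------------------
    def _kmeans_init(self, x: np.ndarray, rng: np.random.Generator):
        n, d = x.shape
        k = self.n_components
        idx = rng.choice(n, size=k, replace=False)
        centers = x[idx].copy()
        for _ in range(25):
            d2 = ((x[:, None, :] - centers[None]) ** 2).sum(-1)
            lab = d2.argmin(1)
            new = np.array([
                x[lab == j].mean(0) if (lab == j).any() else centers[j]
                for j in range(k)])
            if np.allclose(new, centers):
                break
            centers = new
        return centers, lab

    def _log_prob(self, x, means, cov_inv, logdet):
        d = x.shape[1]
        lp = np.empty((x.shape[0], self.n_components))
        for j in range(self.n_components):
            diff = x - means[j]
            maha = np.einsum("ni,ij,nj->n", diff, cov_inv, diff)
            lp[:, j] = -0.5 * (d * np.log(2 * np.pi) + logdet + maha)
        return lp

    def _safe_inv(self, cov):
        try:
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:
                raise np.linalg.LinAlgError
            return np.linalg.inv(cov), logdet
        except np.linalg.LinAlgError:
            warnings.warn("singular shared covariance; ridge-regularized")
            cov = cov + self.ridge * np.eye(cov.shape[0]) * (
                np.trace(cov) + 1.0)
            sign, logdet = np.linalg.slogdet(cov)
            return np.linalg.inv(cov), logdet

    # -- API -----------------------------------------------------------
    def fit(self, x: np.ndarray) -> "GaussianMixtureEEE":
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        n, d = x.shape
        if n < self.n_components:
            raise ValueError("fewer points than components")
        rng = np.random.default_rng(self.random_state)
        means, lab = self._kmeans_init(x, rng)
        weights = np.array([(lab == j).mean() for j in range(self.n_components)])
        weights = np.clip(weights, 1e-6, None)
        weights /= weights.sum()
        cov = np.cov(x - means[lab], rowvar=False).reshape(d, d)
        if not np.all(np.isfinite(cov)) or np.allclose(cov, 0):
            cov = np.eye(d) * max(self.ridge, 1e-12)

        prev = -np.inf
        self.converged_ = False
        for it in range(self.max_iter):
            cov_inv, logdet = self._safe_inv(cov)
            lp = self._log_prob(x, means, cov_inv, logdet) + np.log(weights)
            norm = logsumexp(lp, axis=1)
            loglik = float(norm.sum())
            resp = np.exp(lp - norm[:, None])
            if loglik - prev < self.tol and it > 0:
                self.converged_ = True
                prev = loglik
                break
            prev = loglik
            nk = resp.sum(0)
            weights = nk / n
            means = (resp.T @ x) / nk[:, None]
            cov = np.zeros((d, d))
            for j in range(self.n_components):
                diff = x - means[j]
                cov += (resp[:, j, None] * diff).T @ diff
            cov /= n
        else:
            warnings.warn("EM did not converge; keeping best state")

        self.means_ = means
        self.covariance_ = cov
        self.weights_ = weights
        self.loglik_ = prev
        cov_inv, logdet = self._safe_inv(cov)
        lp = self._log_prob(x, means, cov_inv, logdet) + np.log(weights)
        self.resp_ = np.exp(lp - logsumexp(lp, axis=1)[:, None])
        self.labels_ = self.resp_.argmax(1)
        self.n_iter_ = it + 1
        return self

    def log_likelihood(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        cov_inv, logdet = self._safe_inv(self.covariance_)
        lp = self._log_prob(x, self.means_, cov_inv, logdet) + np.log(
            self.weights_)
        return float(logsumexp(lp, axis=1).sum())
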