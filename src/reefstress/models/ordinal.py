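"""Proportional-odds cumulative-logit regression by maximum likelihood.

Parameterization: P(Y ≤ j | x) = logistic(θ_j − x·β) with strictly
increasing cutpoints θ_1 < … < θ_{J−1}, so a *positive* slope means the
covariate pushes the response toward the *higher* (more bleached)
categories.  The cutpoints are optimised on an increments scale
(θ_1, log Δ_2, …) to keep the ordering, with analytic gradients; the
covariance matrix comes from the numerically differentiated observed
information in the natural (θ, β) space.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from ..errors import ConvergenceError

__all__ = ["ProportionalOddsLogit"]


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _unpack(phi, n_cut):
    theta = np.empty(n_cut)
    theta[0] = phi[0]
    if n_cut > 1:
        theta[1:] = phi[0] + np.cumsum(np.exp(phi[1:n_cut]))
    return theta, phi[n_cut:]


def _nll_grad_natural(theta, beta, X, j_of):
    """Negative log-likelihood and its gradient in (θ, β) space."""
    n_cut = len(theta)
    eta = X @ beta
    # cumulative probabilities gamma_j for j = 1..J-1 at each obs
    gamma = _sigmoid(theta[None, :] - eta[:, None])  # n x n_cut
    upper = np.concatenate([gamma, np.ones((len(eta), 1))], axis=1)
    lower = np.concatenate([np.zeros((len(eta), 1)), gamma], axis=1)
    probs = upper - lower
    pj = np.clip(probs[np.arange(len(eta)), j_of], 1e-300, None)
    nll = -float(np.sum(np.log(pj)))

    # derivative of gamma wrt its own theta: g' = gamma (1 - gamma)
    gprime = gamma * (1.0 - gamma)
    # d log p_j / d theta_k: +g'_k/p if k == j (upper bound), -g'_k/p if k == j-1
    inv_p = 1.0 / pj
    grad_theta = np.zeros(n_cut)
    d_eta = np.zeros(len(eta))
    for k in range(n_cut):
        is_upper = (j_of == k).astype(float)      # category j has upper cut k = j
        is_lower = (j_of == k + 1).astype(float)  # category j has lower cut k = j-1
        contrib = (is_upper - is_lower) * gprime[:, k] * inv_p
        grad_theta[k] = -float(np.sum(contrib))
        d_eta -= contrib  # per-obs d log p / d eta (eta enters with sign opposite to theta)
    grad_beta = -(X.T @ d_eta)
    return nll, grad_theta, grad_beta, probs


class ProportionalOddsLogit(BaseEstimator):
    """Ordinal proportional-odds regression.

    Attributes after ``fit``: ``cutpoints_`` (increasing array of length
    J−1), ``coef_`` (Series of slopes), ``loglik_``, ``vcov_`` (over
    cutpoints then slopes), ``n_``, ``classes_``, ``converged_``,
    ``separation_flag_``.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 200, separation_bound: float = 15.0):
        self.tol = tol
        self.max_iter = max_iter
        self.separation_bound = separation_bound

    def _prepare(self, X):
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), list(X.columns)
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa[:, None]
        return Xa, [f"x{i}" for i in range(Xa.shape[1])]

    def fit(self, X, y):
        Xa, names = self._prepare(X)
        y = np.asarray(y)
        classes, j_of = np.unique(y, return_inverse=True)
        J = len(classes)
        if J < 3:
            raise ValueError("ordinal fit needs >=3 observed response levels")
        n, p = Xa.shape
        n_cut = J - 1
        if n <= p + n_cut:
            raise ValueError("need more observations than parameters")

        # start at empirical cumulative logits, beta = 0
        freq = np.bincount(j_of, minlength=J) / n
        cum = np.clip(np.cumsum(freq)[:-1], 1e-6, 1 - 1e-6)
        theta0 = np.log(cum / (1.0 - cum))
        # strictly increasing by construction of cumulative frequencies
        phi0 = np.empty(n_cut + p)
        phi0[0] = theta0[0]
        if n_cut > 1:
            phi0[1:n_cut] = np.log(np.maximum(np.diff(theta0), 1e-3))
        phi0[n_cut:] = 0.0

        def objective(phi):
            theta, beta = _unpack(phi, n_cut)
            nll, g_t, g_b, _ = _nll_grad_natural(theta, beta, Xa, j_of)
            # chain rule to the increments scale
            g_phi = np.empty_like(phi)
            g_phi[0] = g_t.sum()
            for k in range(1, n_cut):
                g_phi[k] = np.sum(g_t[k:]) * np.exp(phi[k])
            g_phi[n_cut:] = g_b
            return nll, g_phi

        res = optimize.minimize(
            objective,
            phi0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": self.max_iter * 10, "ftol": 1e-14, "gtol": 1e-9},
        )
        theta, beta = _unpack(res.x, n_cut)
        nll_final = res.fun
        # declared converged when a further Newton-style polish cannot move
        # the log-likelihood by more than tol
        probe = optimize.minimize(
            objective, res.x, jac=True, method="L-BFGS-B",
            options={"maxiter": 5, "ftol": 1e-16, "gtol": 1e-12},
        )
        converged = abs(probe.fun - nll_final) < self.tol
        if probe.fun < nll_final:
            theta, beta = _unpack(probe.x, n_cut)
            nll_final = probe.fun

        sd = Xa.std(axis=0)
        sd[sd == 0.0] = 1.0
        separated = bool(np.any(np.abs(beta * sd) > self.separation_bound))
        if not converged and not separated:
            raise ConvergenceError(
                "ordinal fit did not converge", last_iterate=(theta, beta)
            )

        # observed information by central differences of the analytic gradient
        def grad_nat(v):
            t, b = v[:n_cut], v[n_cut:]
            _, g_t, g_b, _ = _nll_grad_natural(t, b, Xa, j_of)
            return np.concatenate([g_t, g_b])

        v0 = np.concatenate([theta, beta])
        dim = len(v0)
        H = np.empty((dim, dim))
        h = 1e-5 * np.maximum(1.0, np.abs(v0))
        for k in range(dim):
            e = np.zeros(dim)
            e[k] = h[k]
            H[:, k] = (grad_nat(v0 + e) - grad_nat(v0 - e)) / (2.0 * h[k])
        H = 0.5 * (H + H.T)
        try:
            vcov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            vcov = np.full((dim, dim), np.nan)

        cut_names = [f"cut_{k + 1}" for k in range(n_cut)]
        self.cutpoints_ = theta
        self.coef_ = pd.Series(beta, index=names)
        self.loglik_ = -float(nll_final)
        self.vcov_ = pd.DataFrame(vcov, index=cut_names + names, columns=cut_names + names)
        self.n_ = n
        self.df_model_ = n_cut + p
        self.classes_ = classes
        self.converged_ = converged
        self.separation_flag_ = separated
        return self

    def predict_proba(self, X):
        """Per-category probabilities, one column per level of ``classes_``."""
        Xa, _ = self._prepare(X)
        eta = Xa @ self.coef_.to_numpy()
        gamma = _sigmoid(self.cutpoints_[None, :] - eta[:, None])
        upper = np.concatenate([gamma, np.ones((len(eta), 1))], axis=1)
        lower = np.concatenate([np.zeros((len(eta), 1)), gamma], axis=1)
        return upper - lower

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
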