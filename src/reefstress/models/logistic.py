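"""Maximum-likelihood logistic regression with separation detection.

A plain Newton-Raphson (IRLS) binomial-family GLM.  Complete or
quasi-complete separation — which the interaction-rich mortality models
are prone to on small cohorts — is flagged when any standardized
coefficient exceeds a configurable bound while the likelihood is still
improving, rather than silently reporting runaway estimates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ..errors import ConvergenceError

__all__ = ["BinomialLogit"]


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class BinomialLogit(BaseEstimator):
    """Binary-response logistic regression fit by Newton-Raphson.

    Attributes after ``fit``: ``coef_`` (Series incl. ``Intercept``),
    ``loglik_``, ``vcov_``, ``n_``, ``converged_``, ``separation_flag_``.
    """

    def __init__(
        self,
        add_intercept: bool = True,
        max_iter: int = 100,
        tol: float = 1e-8,
        separation_bound: float = 15.0,
    ):
        self.add_intercept = add_intercept
        self.max_iter = max_iter
        self.tol = tol
        self.separation_bound = separation_bound

    def _prepare(self, X):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            if Xa.ndim == 1:
                Xa = Xa[:, None]
            names = [f"x{i}" for i in range(Xa.shape[1])]
        if self.add_intercept:
            Xa = np.column_stack([np.ones(Xa.shape[0]), Xa])
            names = ["Intercept"] + names
        return Xa, names

    def fit(self, X, y):
        Xa, names = self._prepare(X)
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("response must be binary 0/1")
        n, p = Xa.shape
        if n <= p:
            raise ValueError("need more observations than parameters")
        # scale used only for separation detection
        sd = Xa.std(axis=0)
        sd[sd == 0.0] = 1.0

        beta = np.zeros(p)
        ll_old = -np.inf
        converged = False
        improving = True
        for _ in range(self.max_iter):
            eta = Xa @ beta
            mu = _sigmoid(eta)
            ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
            w = mu * (1.0 - mu)
            grad = Xa.T @ (y - mu)
            H = (Xa * w[:, None]).T @ Xa
            try:
                step = np.linalg.solve(H + 1e-10 * np.eye(p), grad)
            except np.linalg.LinAlgError:
                raise ConvergenceError("singular information matrix", last_iterate=beta)
            # step-halving if the likelihood would decrease
            new = beta + step
            for _half in range(30):
                eta_n = Xa @ new
                ll_new = float(np.sum(y * eta_n - np.logaddexp(0.0, eta_n)))
                if ll_new >= ll - 1e-12:
                    break
                new = beta + (new - beta) / 2.0
            beta = new
            improving = ll_new > ll_old + 1e-12
            if abs(ll_new - ll_old) < self.tol:
                converged = True
                ll_old = ll_new
                break
            ll_old = ll_new

        beta_std = beta * sd
        separated = bool(np.any(np.abs(beta_std) > self.separation_bound) and improving)
        eta = Xa @ beta
        mu = _sigmoid(eta)
        w = mu * (1.0 - mu)
        H = (Xa * w[:, None]).T @ Xa
        try:
            vcov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            vcov = np.full((p, p), np.nan)
        self.coef_ = pd.Series(beta, index=names)
        self.loglik_ = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        self.vcov_ = pd.DataFrame(vcov, index=names, columns=names)
        self.n_ = n
        self.df_model_ = p
        self.converged_ = converged or separated
        self.separation_flag_ = separated
        return self

    def predict_proba(self, X):
        Xa, _ = self._prepare(X)
        p1 = _sigmoid(Xa @ self.coef_.to_numpy())
        return np.column_stack([1.0 - p1, p1])
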