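"""Colony-level random-intercept sensitivity check.

Repeated surveys of the same colony are correlated; the fixed-effects
models treat rows as independent, a choice this check validates by
refitting the selected model with a colony-level random intercept.  The marginal likelihood integrates the random effect
with Gauss-Hermite quadrature (exact enough for a scalar intercept),
and the variance is tested against zero with a boundary-corrected
likelihood-ratio test (p-value halved, since σ² = 0 lies on the
parameter-space boundary).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ..errors import NotApplicableError
from .design import build_design
from .selection import TermModel

__all__ = ["random_intercept_check"]


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _binary_cond_loglik(eta, y):
    return y * eta - np.logaddexp(0.0, eta)


def _ordinal_cond_logprob(eta, y, theta):
    gamma_hi = np.where(
        y[:, None] == len(theta), 1.0, _sigmoid(theta[np.minimum(y, len(theta) - 1)][:, None] - eta)
    )
    gamma_lo = np.where(y[:, None] == 0, 0.0, _sigmoid(theta[np.maximum(y - 1, 0)][:, None] - eta))
    return np.log(np.clip(gamma_hi - gamma_lo, 1e-300, None))


def random_intercept_check(
    model: TermModel,
    cluster_col: str = "colony_id",
    n_quad: int = 15,
):
    """Refit a selected model with a cluster random intercept.

    Returns a dict with the random-intercept standard deviation
    estimate, the boundary-corrected LRT against σ = 0, the fixed
    effects with and without the random intercept, and whether any
    fixed-effect sign changed.  Raises
    :class:`~reefstress.errors.NotApplicableError` when no cluster has
    repeated rows.
    """
    frame = model.frame
    clusters, cl_idx = np.unique(frame[cluster_col].to_numpy(), return_inverse=True)
    if len(clusters) == len(frame):
        raise NotApplicableError("no repeated rows per cluster")
    X, _ = build_design(frame, model.terms)
    Xa = X.to_numpy(dtype=float)
    y = np.asarray(frame[model.response].to_numpy())

    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    # probabilists' Gauss-Hermite: integral f(z) phi(z) dz ~ sum (w/sqrt(2pi)) f(x)
    logw = np.log(weights) - 0.5 * np.log(2.0 * np.pi)
    # marginal loglik: sum_c log sum_q w_q exp(sum_i logp(y_i | eta_i + sigma z_q))
    family = model.family
    n_cut = len(model.estimator.cutpoints_) if family == "ordinal" else 0
    p = Xa.shape[1]

    def nll(params):
        if family == "ordinal":
            theta = np.sort(params[:n_cut])
            beta = params[n_cut : n_cut + p]
            intercept = 0.0
        else:
            intercept = params[0]
            beta = params[1 : 1 + p]
            theta = None
        log_sigma = params[-1]
        sigma = np.exp(log_sigma)
        eta0 = Xa @ beta + intercept
        eta_q = eta0[:, None] + sigma * nodes[None, :]  # n x q
        if family == "ordinal":
            lp = _ordinal_cond_logprob(eta_q, y.astype(int), theta)
        else:
            lp = _binary_cond_loglik(eta_q, y[:, None].astype(float))
        # sum conditional log-probs within cluster, per node
        ncl = len(clusters)
        cl_lp = np.zeros((ncl, n_quad))
        np.add.at(cl_lp, cl_idx, lp)
        tot = float(np.sum(_logsumexp(cl_lp + logw[None, :], axis=1)))
        return -tot

    est = model.estimator
    if family == "ordinal":
        start = np.concatenate([est.cutpoints_, est.coef_.to_numpy(), [np.log(0.1)]])
    else:
        start = np.concatenate([est.coef_.to_numpy(), [np.log(0.1)]])
    res = optimize.minimize(nll, start, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
    res2 = optimize.minimize(nll, res.x, method="Powell",
                             options={"maxiter": 2000, "ftol": 1e-10})
    best = res2 if res2.fun < res.fun else res
    sigma_hat = float(np.exp(best.x[-1]))
    ll_mixed = -float(best.fun)
    ll_fixed = model.loglik
    lrt_stat = max(0.0, 2.0 * (ll_mixed - ll_fixed))
    p_boundary = 0.5 * float(stats.chi2.sf(lrt_stat, 1))

    if family == "ordinal":
        fixed_mixed = pd.Series(best.x[n_cut : n_cut + p], index=X.columns)
        fixed_plain = est.coef_
    else:
        fixed_mixed = pd.Series(best.x[1 : 1 + p], index=X.columns)
        fixed_plain = est.coef_.drop("Intercept")
    sign_changed = bool(
        np.any(np.sign(fixed_mixed.to_numpy()) != np.sign(fixed_plain.reindex(X.columns).to_numpy()))
        and np.any(np.abs(fixed_plain.reindex(X.columns).to_numpy()) > 1e-6)
    )
    return {
        "sigma": sigma_hat,
        "variance": sigma_hat**2,
        "lrt": lrt_stat,
        "p": p_boundary,
        "loglik_mixed": ll_mixed,
        "loglik_fixed": ll_fixed,
        "fixed_effects_mixed": fixed_mixed,
        "fixed_effects_fixed": fixed_plain,
        "conclusion_changed": sign_changed,
    }


def _logsumexp(a, axis=None):
    m = np.max(a, axis=axis, keepdims=True)
    return np.squeeze(m, axis=axis) + np.log(np.sum(np.exp(a - m), axis=axis))
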