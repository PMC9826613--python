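"""Proportional-odds diagnostics and multiplicity-adjusted group contrasts.

The Brant test follows the classical construction: fit the J−1
threshold-specific binary logistic regressions of 1{Y > j} on the same
design, assemble the joint asymptotic covariance of their slope
estimates from the shared observations, and test equality of slopes
across thresholds with a Wald χ² — per variable and for the whole
model (df = (J−2) × number of slopes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ..errors import NotApplicableError
from .logistic import BinomialLogit

__all__ = ["BrantResult", "brant_test", "pairwise_groups"]


@dataclass
class BrantResult:
    """Brant-test outcome: whole-model and per-variable Wald χ² tests."""

    chi2: float
    df: int
    p: float
    per_variable: pd.DataFrame  # index variable, columns chi2/df/p
    separation_flag: bool = False

    def to_frame(self) -> pd.DataFrame:
        whole = pd.DataFrame(
            {"chi2": [self.chi2], "df": [self.df], "p": [self.p]}, index=["Whole model"]
        )
        return pd.concat([whole, self.per_variable])


def brant_test(fit, X, y) -> BrantResult:
    """Brant test of the proportional-odds assumption.

    ``fit`` is a fitted :class:`~reefstress.models.ordinal.ProportionalOddsLogit`
    (used for its class ordering), ``X`` the slope design (DataFrame)
    and ``y`` the ordinal response.  Raises
    :class:`~reefstress.errors.NotApplicableError` for a binary response.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(Xa.shape[1])]
    y = np.asarray(y)
    classes = fit.classes_ if fit is not None else np.unique(y)
    J = len(classes)
    if J < 3:
        raise NotApplicableError("Brant test needs >=3 response levels")
    n, p = Xa.shape
    n_thr = J - 1
    Z = np.column_stack([np.ones(n), Xa])  # intercept-augmented design

    betas = []  # full coefficient vectors incl. intercept
    pis = []
    separated = False
    for j in range(n_thr):
        zj = (y > classes[j]).astype(float)
        m = BinomialLogit(add_intercept=False).fit(Z, zj)
        separated = separated or m.separation_flag_
        betas.append(m.coef_.to_numpy())
        pis.append(m.predict_proba(Z)[:, 1])

    # joint covariance of the stacked estimates (Brant 1990): for j <= l,
    # cov = (Z'WjjZ)^-1 (Z'WjlZ) (Z'WllZ)^-1 with wjl = pi_l - pi_j pi_l
    npar = p + 1
    V = np.zeros((n_thr * npar, n_thr * npar))
    inv_info = []
    for j in range(n_thr):
        wjj = pis[j] * (1.0 - pis[j])
        inv_info.append(np.linalg.inv((Z * wjj[:, None]).T @ Z))
    for j in range(n_thr):
        for l in range(j, n_thr):
            wjl = pis[l] - pis[j] * pis[l]
            block = inv_info[j] @ ((Z * wjl[:, None]).T @ Z) @ inv_info[l]
            V[j * npar : (j + 1) * npar, l * npar : (l + 1) * npar] = block
            if l != j:
                V[l * npar : (l + 1) * npar, j * npar : (j + 1) * npar] = block.T

    # drop intercepts: keep slope entries only
    keep = np.concatenate([np.arange(1, npar) + j * npar for j in range(n_thr)])
    beta_s = np.concatenate([b[1:] for b in betas])
    Vs = V[np.ix_(keep, keep)]

    def wald(idx_within):
        """χ² for slope equality across thresholds for given slope indices."""
        k = len(idx_within)
        rows = []
        for j in range(1, n_thr):
            for i in idx_within:
                r = np.zeros(n_thr * p)
                r[i] = 1.0
                r[j * p + i] = -1.0
                rows.append(r)
        D = np.array(rows)
        diff = D @ beta_s
        cov = D @ Vs @ D.T
        stat = float(diff @ np.linalg.solve(cov, diff))
        df = (n_thr - 1) * k
        return stat, df, float(stats.chi2.sf(stat, df))

    chi2, df, pval = wald(list(range(p)))
    per = {}
    for i, name in enumerate(names):
        per[name] = wald([i])
    per_df = pd.DataFrame(per, index=["chi2", "df", "p"]).T
    per_df["df"] = per_df["df"].astype(int)
    return BrantResult(chi2=chi2, df=df, p=pval, per_variable=per_df, separation_flag=separated)


def _single_step_adjust(zs: np.ndarray, C: np.ndarray, vcov: np.ndarray) -> np.ndarray:
    """Single-step max-|Z| adjusted p-values for contrasts C over N(0, vcov).

    The joint distribution of the contrast z-statistics is degenerate
    (pairwise contrasts are linearly dependent), so the reference
    distribution of max_k |Z_k| is evaluated by quasi-Monte Carlo in the
    underlying coefficient space — deterministic via a fixed Sobol seed.
    """
    if len(zs) == 1:
        return 2.0 * stats.norm.sf(np.abs(zs))
    # factor the coefficient covariance (PSD-safe)
    w, V = np.linalg.eigh(vcov)
    w = np.clip(w, 0.0, None)
    L = V * np.sqrt(w)[None, :]
    se = np.sqrt(np.einsum("ij,jk,ik->i", C, vcov, C))
    se[se == 0.0] = np.inf
    A = (C / se[:, None]) @ L  # maps iid normals to standardized contrasts
    sob = stats.qmc.Sobol(d=vcov.shape[0], scramble=True, rng=np.random.default_rng(20160903))
    u = sob.random_base2(m=16)
    zmat = stats.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12)) @ A.T
    maxabs = np.abs(zmat).max(axis=1)
    return np.array([float(np.mean(maxabs >= abs(z))) for z in zs])


def pairwise_groups(model, factor: str, adjust: str = "single-step") -> pd.DataFrame:
    """All pairwise contrasts of a factor's levels on the link scale.

    ``model`` is a fitted :class:`~reefstress.models.selection.TermModel`
    containing ``factor`` as a term.  Contrast estimates and Wald z use
    the fitted covariance; the multiplicity adjustment is the
    single-step multivariate-normal ("Tukey-style") method by default,
    with ``'holm'`` and ``'bonferroni'`` available.  Returns a DataFrame
    with columns ``estimate, se, z, p, p_adj, method``.
    """
    if factor not in model.term_columns:
        raise ValueError(f"factor {factor!r} not a term of the model")
    dummy_cols = model.term_columns[factor]
    if len(dummy_cols) == 0:
        return pd.DataFrame(columns=["estimate", "se", "z", "p", "p_adj", "method"])
    # recover level names: reference level is the one without a dummy
    levels = [c.split("[T.")[1][:-1] for c in dummy_cols]
    ref = sorted(set(model.frame[factor].astype(str)) - set(levels))[0]
    all_levels = [ref] + levels

    coef = model.estimator.coef_
    vcov = model.estimator.vcov_
    # coefficient vector indexed by level (reference = 0 with no variance)
    def colname(lev):
        return None if lev == ref else f"{factor}[T.{lev}]"

    contrasts, ests, variances, vecs = [], [], [], []
    names_in_vcov = list(vcov.index)
    for i in range(len(all_levels)):
        for j in range(i + 1, len(all_levels)):
            li, lj = all_levels[i], all_levels[j]
            v = np.zeros(len(names_in_vcov))
            est = 0.0
            for lev, sign in ((li, 1.0), (lj, -1.0)):
                c = colname(lev)
                if c is not None:
                    v[names_in_vcov.index(c)] = sign
                    est += sign * coef[c]
            contrasts.append(f"{li} - {lj}")
            ests.append(est)
            vecs.append(v)
            variances.append(float(v @ vcov.to_numpy() @ v))

    ses = np.sqrt(np.array(variances))
    zs = np.array(ests) / ses
    praw = 2.0 * stats.norm.sf(np.abs(zs))
    C = np.array(vecs)

    if adjust in ("single-step", "mvt"):
        p_adj = np.maximum(_single_step_adjust(zs, C, vcov.to_numpy()), praw)
        method = "single-step multivariate normal"
    elif adjust == "holm":
        m = len(praw)
        p_adj = np.empty(m)
        prev = 0.0
        for rank, idx in enumerate(np.argsort(praw)):
            val = min(1.0, (m - rank) * praw[idx])
            prev = max(prev, val)
            p_adj[idx] = prev
        method = "Holm"
    elif adjust == "bonferroni":
        p_adj = np.minimum(1.0, praw * len(praw))
        method = "Bonferroni"
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    return pd.DataFrame(
        {
            "estimate": ests,
            "se": ses,
            "z": zs,
            "p": praw,
            "p_adj": p_adj,
            "method": method,
        },
        index=pd.Index(contrasts, name="contrast"),
    )
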