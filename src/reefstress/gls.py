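"""Generalized least squares with AR(1) errors, fit by maximum likelihood.

Used to contrast pre-peak heating rates between two summers: daily mean
temperature is regressed on time (days), year, and their interaction,
with a first-order autoregressive correlation structure *within* each
year; a Wald test on the time×year coefficient decides whether the
heating rate differs between the years.

The fit is full ML (not REML): for a candidate autocorrelation ρ the
model is whitened by the Prais-Winsten transform per group (first
observation scaled by sqrt(1−ρ²), later ones quasi-differenced), β and
the innovation variance are profiled out in closed form, and the
resulting profile log-likelihood is maximised over ρ ∈ (−1, 1).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .errors import ConvergenceError

__all__ = ["GlsAr1", "fit_gls_ar1", "heating_rate_design"]

_RHO_BOUND = 0.999


def _whiten(X, y, groups, rho):
    Xw = X.copy()
    yw = y.copy()
    scale = np.sqrt(1.0 - rho**2)
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        Xw[idx[0]] = X[idx[0]] * scale
        yw[idx[0]] = y[idx[0]] * scale
        Xw[idx[1:]] = X[idx[1:]] - rho * X[idx[:-1]]
        yw[idx[1:]] = y[idx[1:]] - rho * y[idx[:-1]]
    return Xw, yw


class GlsAr1(BaseEstimator):
    """ML linear regression with AR(1) errors within groups.

    Parameters
    ----------
    add_intercept : bool
        Prepend an intercept column to the design.
    rho_bound : float
        |ρ| is constrained below this bound; estimates within 0.02 of it
        trigger a boundary warning.

    Attributes (after :meth:`fit`)
    ------------------------------
    coef_ : pandas.Series mapping term → estimate.
    rho_ : AR(1) correlation estimate.
    sigma2_ : innovation variance estimate (ML).
    loglik_ : maximised log-likelihood.
    vcov_ : DataFrame, asymptotic covariance of ``coef_`` given ρ̂.
    n_ : number of observations.
    """

    def __init__(self, add_intercept: bool = True, rho_bound: float = _RHO_BOUND):
        self.add_intercept = add_intercept
        self.rho_bound = rho_bound

    def _profile(self, rho, X, y, groups):
        Xw, yw = _whiten(X, y, groups, rho)
        beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        if rank < X.shape[1]:
            raise ConvergenceError("singular whitened design", last_iterate=rho)
        resid = yw - Xw @ beta
        rss = float(resid @ resid)
        n = len(y)
        g = len(np.unique(groups))
        sigma2 = rss / n
        ll = (
            -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
            + 0.5 * g * np.log(1.0 - rho**2)
        )
        return ll, beta, sigma2, Xw

    def fit(self, X, y, groups=None):
        """Fit by profiling the log-likelihood over ρ.

        ``X`` may be a DataFrame (column names become term labels) or an
        array; ``groups`` marks independent AR(1) segments (e.g. years)
        — a single segment if omitted.  Observations must be
        time-ordered within each group.
        """
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xa = X.to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            if Xa.ndim == 1:
                Xa = Xa[:, None]
            names = [f"x{i}" for i in range(Xa.shape[1])]
        y = np.asarray(y, dtype=float)
        if self.add_intercept:
            Xa = np.column_stack([np.ones(len(y)), Xa])
            names = ["Intercept"] + names
        groups = np.zeros(len(y), dtype=int) if groups is None else np.asarray(groups)
        if len(y) < Xa.shape[1] + 2:
            raise ValueError("need at least p + 2 observations")

        res = optimize.minimize_scalar(
            lambda r: -self._profile(r, Xa, y, groups)[0],
            bounds=(-self.rho_bound, self.rho_bound),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if not res.success:
            raise ConvergenceError("rho optimisation failed", last_iterate=res.x)
        rho = float(res.x)
        if abs(rho) > self.rho_bound - 0.02:
            warnings.warn(f"AR1 estimate near boundary: rho = {rho:.3f}", stacklevel=2)
        ll, beta, sigma2, Xw = self._profile(rho, Xa, y, groups)
        xtx_inv = np.linalg.inv(Xw.T @ Xw)
        self.coef_ = pd.Series(beta, index=names)
        self.rho_ = rho
        self.sigma2_ = float(sigma2)
        self.loglik_ = float(ll)
        self.vcov_ = pd.DataFrame(sigma2 * xtx_inv, index=names, columns=names)
        self.n_ = len(y)
        return self

    def wald(self, term: str):
        """Wald z test of a single coefficient against zero → (z, p)."""
        se = float(np.sqrt(self.vcov_.loc[term, term]))
        z = float(self.coef_[term] / se)
        return z, float(2.0 * stats.norm.sf(abs(z)))


def heating_rate_design(daily_a: pd.DataFrame, daily_b: pd.DataFrame, windows=None):
    """Build the time/year/time×year design for the heating-rate contrast.

    Each year's daily means are restricted to its pre-peak 3-month span
    (computed by :func:`reefstress.envtests.heating_rate2_window` unless
    explicit ``windows`` are given); time is days from the window start.
    Returns ``(X: DataFrame, y, groups)``.
    """
    from .envtests import heating_rate2_window

    frames = []
    for k, daily in enumerate((daily_a, daily_b)):
        lo, hi = windows[k] if windows is not None else heating_rate2_window(daily)
        d = daily[daily["valid"]]
        d = d[(np.array(list(d.index)) >= lo) & (np.array(list(d.index)) <= hi)]
        t = np.array([(x - lo).days for x in d.index], dtype=float)
        frames.append(
            pd.DataFrame(
                {"time": t, "year": float(k), "stsp": d["mean_temp"].to_numpy()}
            )
        )
    df = pd.concat(frames, ignore_index=True)
    X = pd.DataFrame(
        {"time": df["time"], "year": df["year"], "time:year": df["time"] * df["year"]}
    )
    groups = df["year"].to_numpy(dtype=int)
    return X, df["stsp"].to_numpy(), groups


def fit_gls_ar1(X, y, groups=None) -> GlsAr1:
    """Functional wrapper: fit :class:`GlsAr1` and return the estimator."""
    return GlsAr1().fit(X, y, groups=groups)
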