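"""Term-level model fitting, likelihood-ratio tests, backward selection.

Backward selection removes, one per round, the single term whose
deletion degrades the log-likelihood least (largest LRT p-value above
α), honouring marginality — an interaction must leave before any of its
main effects — and stops when every remaining term is significant at α.
Every comparison is recorded in a trace table whose columns mirror the
usual reporting shape (term, N, df, LRT, p).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ..errors import ConvergenceError
from .design import build_design, removable_terms
from .logistic import BinomialLogit
from .ordinal import ProportionalOddsLogit

__all__ = ["TermModel", "LrtResult", "fit_terms", "lrt", "backward_select"]


@dataclass
class LrtResult:
    """One likelihood-ratio comparison (full vs nested)."""

    lrt: float
    df: int
    p: float
    dropped_term: str | None = None

    def to_dict(self):
        return {"lrt": self.lrt, "df": self.df, "p": self.p, "dropped_term": self.dropped_term}


class TermModel:
    """A fitted model bound to its frame, response and term list.

    Thin orchestration layer over :class:`ProportionalOddsLogit` /
    :class:`BinomialLogit`: it owns the term → design-column mapping so
    that selection and diagnostics can refit on term subsets of the
    *same* rows.
    """

    def __init__(self, frame: pd.DataFrame, response: str, terms, family: str, **fit_kwargs):
        if family not in ("ordinal", "binomial"):
            raise ValueError("family must be 'ordinal' or 'binomial'")
        self.frame = frame
        self.response = response
        self.terms = list(terms)
        self.family = family
        self._fit_kwargs = fit_kwargs
        self.X, self.term_columns = build_design(frame, self.terms)
        self.y = frame[response].to_numpy()
        if family == "ordinal":
            self.estimator = ProportionalOddsLogit(**fit_kwargs).fit(self.X, self.y)
        else:
            self.estimator = BinomialLogit(**fit_kwargs).fit(self.X, self.y)

    @property
    def loglik(self) -> float:
        return self.estimator.loglik_

    @property
    def n(self) -> int:
        return self.estimator.n_

    @property
    def n_params(self) -> int:
        return self.estimator.df_model_

    def without(self, term: str) -> "TermModel":
        """Refit on the same rows with ``term`` removed."""
        return TermModel(
            self.frame,
            self.response,
            [t for t in self.terms if t != term],
            self.family,
            **self._fit_kwargs,
        )


def fit_terms(frame, response, terms, family, **kw) -> TermModel:
    return TermModel(frame, response, terms, family, **kw)


def lrt(full: TermModel, nested: TermModel) -> LrtResult:
    """Likelihood-ratio test of a nested model against a fuller one."""
    if not set(nested.terms) <= set(full.terms):
        raise ValueError("models are not nested")
    if nested.n != full.n:
        raise ValueError("models were fitted on different numbers of rows")
    df = full.n_params - nested.n_params
    if df < 0:
        raise ValueError("nested model must not have more parameters")
    stat = max(0.0, 2.0 * (full.loglik - nested.loglik))
    if df == 0:  # identical parameterizations: no evidence either way
        dropped = set(full.terms) - set(nested.terms)
        return LrtResult(lrt=stat, df=0, p=1.0, dropped_term=dropped.pop() if len(dropped) == 1 else None)
    dropped = set(full.terms) - set(nested.terms)
    return LrtResult(
        lrt=stat,
        df=df,
        p=float(stats.chi2.sf(stat, df)),
        dropped_term=dropped.pop() if len(dropped) == 1 else None,
    )


def backward_select(
    frame: pd.DataFrame,
    response: str,
    full_terms,
    family: str,
    alpha: float = 0.05,
    compare_to: str = "current",
    **fit_kwargs,
):
    """Backward model selection by likelihood-ratio tests.

    Starting from the full term list, each round tests the removal of
    every marginality-respecting candidate (against the current model by
    default, or always against the full model with
    ``compare_to='full'``), drops the single term with the largest
    p-value above ``alpha``, and repeats until all candidates are
    significant.  Returns ``(best: TermModel, trace: DataFrame)``; the
    trace has one row per comparison with columns
    ``round, term, n, df, lrt, p, dropped``.
    """
    if compare_to not in ("current", "full"):
        raise ValueError("compare_to must be 'current' or 'full'")
    try:
        full = TermModel(frame, response, full_terms, family, **fit_kwargs)
    except ConvergenceError as err:
        raise ConvergenceError(
            f"full model for {response!r} did not converge", last_iterate=err.last_iterate
        ) from err
    reference = full
    current = full
    trace = []
    rnd = 0
    while current.terms:
        rnd += 1
        candidates = removable_terms(current.terms)
        results = {}
        for term in candidates:
            nested = current.without(term)
            comp = lrt(reference, nested) if compare_to == "full" else lrt(current, nested)
            results[term] = (comp, nested)
        worst = max(results, key=lambda t: results[t][0].p)
        for term in candidates:
            comp, _ = results[term]
            trace.append(
                {
                    "round": rnd,
                    "term": term,
                    "n": current.n,
                    "df": comp.df,
                    "lrt": comp.lrt,
                    "p": comp.p,
                    "dropped": term == worst and comp.p > alpha,
                }
            )
        comp, nested = results[worst]
        if comp.p > alpha:
            current = nested
            if compare_to == "full":
                reference = full
        else:
            break
    return current, pd.DataFrame(trace)
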