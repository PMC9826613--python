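"""Term-based design matrices (reference-coded factors, interactions).

A *term* is a covariate name or a colon-joined interaction such as
``"size:time"``.  Categorical columns are expanded to treatment-coded
dummies against the first level in sorted order; an interaction's design
columns are the element-wise products of its components' columns.  The
intercept is not part of any term — each model supplies its own.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["build_design", "term_factors", "removable_terms"]


def term_factors(term: str) -> frozenset:
    return frozenset(term.split(":"))


def _main_effect_columns(frame: pd.DataFrame, name: str) -> pd.DataFrame:
    col = frame[name]
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        levels = sorted(pd.unique(col.astype(str)))
        out = {}
        for lev in levels[1:]:
            out[f"{name}[T.{lev}]"] = (col.astype(str) == lev).astype(float)
        return pd.DataFrame(out, index=frame.index)
    return pd.DataFrame({name: col.astype(float)}, index=frame.index)


def build_design(frame: pd.DataFrame, terms):
    """Expand ``terms`` over ``frame`` into a numeric design matrix.

    Returns ``(X, term_columns)`` where ``term_columns`` maps each term
    to its design-column names (several for a factor or an interaction
    involving one).
    """
    blocks = []
    term_columns = {}
    main_cache = {}

    def main(name):
        if name not in main_cache:
            if name not in frame.columns:
                raise KeyError(f"covariate {name!r} not in frame")
            main_cache[name] = _main_effect_columns(frame, name)
        return main_cache[name]

    for term in terms:
        parts = term.split(":")
        block = main(parts[0])
        for p in parts[1:]:
            nxt = main(p)
            cols = {}
            for c1 in block.columns:
                for c2 in nxt.columns:
                    cols[f"{c1}:{c2}"] = block[c1].to_numpy() * nxt[c2].to_numpy()
            block = pd.DataFrame(cols, index=frame.index)
        blocks.append(block)
        term_columns[term] = list(block.columns)
    if blocks:
        X = pd.concat(blocks, axis=1)
    else:
        X = pd.DataFrame(index=frame.index)
    return X, term_columns


def removable_terms(terms):
    """Terms whose removal respects marginality: a main effect (or
    lower-order interaction) is not removable while a higher-order
    interaction contains it."""
    out = []
    for t in terms:
        ft = term_factors(t)
        if any(ft < term_factors(other) for other in terms if other != t):
            continue
        out.append(t)
    return out
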