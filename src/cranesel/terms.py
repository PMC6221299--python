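"""Small model-term language and design-matrix construction.

Model structures are written as lists of terms over named covariates:

* ``"water"`` — a main effect;
* ``"width:water"`` — a product interaction of continuous covariates;
* ``"width*water*sandbar"`` — factorial expansion into all main effects and
  all two- and three-way interactions.

Categorical covariates expand to one-hot (dummy) columns against a declared
reference level (alfalfa/hay for land use, private for ownership).
Continuous covariates may be z-score standardized, with the transform
returned so that prediction surfaces can reuse it.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError


def expand_terms(terms) -> list[tuple[str, ...]]:
    """Expand a term list into an ordered, de-duplicated list of tuples.

    Each returned tuple holds the base covariate names entering a product;
    singletons are main effects. ``a*b`` expands to ``a, b, a:b``;
    factorial expansion always includes lower-order terms ahead of
    higher-order ones.
    """
    out: list[tuple[str, ...]] = []

    def add(t: tuple[str, ...]):
        if t not in out:
            out.append(t)

    for term in terms:
        term = term.strip()
        if "*" in term:
            parts = tuple(p.strip() for p in term.split("*"))
            for order in range(1, len(parts) + 1):
                for combo in combinations(parts, order):
                    add(combo)
        elif ":" in term:
            add(tuple(p.strip() for p in term.split(":")))
        else:
            add((term,))
    return out


def term_label(term: tuple[str, ...]) -> str:
    return ":".join(term)


def build_design_matrix(
    df: pd.DataFrame,
    terms,
    categorical: dict | None = None,
    standardize: bool = True,
    constants: dict | None = None,
):
    """Build a design matrix from a covariate frame.

    Parameters
    ----------
    df : DataFrame
        One row per design row, columns holding covariates.
    terms : list of str
        Term language expressions (see module docstring).
    categorical : dict, optional
        Mapping ``name -> (levels, reference)`` for categorical covariates.
        Non-reference levels each contribute a dummy column ``name[level]``.
    standardize : bool
        Z-score continuous columns. Categorical dummies are never scaled.
    constants : dict, optional
        Mapping ``name -> (mean, sd)`` reused for standardization (e.g.,
        when scoring new data with a fitted model). Computed from ``df``
        when absent.

    Returns
    -------
    X : ndarray (n, p)
    names : list of str
    constants_used : dict
    """
    categorical = categorical or {}
    expanded = expand_terms(terms)
    constants_used: dict[str, tuple] = {}

    def continuous_column(name: str) -> np.ndarray:
        if name not in df.columns:
            raise ConfigurationError(f"term references unknown covariate {name!r}")
        x = df[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise ConfigurationError(f"covariate {name!r} contains non-finite values")
        if standardize:
            if constants is not None and name in constants:
                m, s = constants[name]
            else:
                m, s = float(x.mean()), float(x.std(ddof=0))
            if s == 0:
                s = 1.0
            constants_used[name] = (m, s)
            x = (x - m) / s
        return x

    cols: list[np.ndarray] = []
    names: list[str] = []
    for term in expanded:
        if len(term) == 1 and term[0] in categorical:
            name = term[0]
            if name not in df.columns:
                raise ConfigurationError(f"term references unknown covariate {name!r}")
            levels, ref = categorical[name]
            vals = df[name].to_numpy()
            unknown = set(np.unique(vals)) - set(levels)
            if unknown:
                raise ConfigurationError(
                    f"covariate {name!r} has levels {sorted(unknown)} not in {levels}"
                )
            for level in levels:
                if level == ref:
                    continue
                cols.append((vals == level).astype(float))
                names.append(f"{name}[{level}]")
        else:
            for name in term:
                if name in categorical:
                    raise ConfigurationError(
                        f"categorical covariate {name!r} cannot enter a product term"
                    )
            x = continuous_column(term[0]).copy()
            for name in term[1:]:
                x = x * continuous_column(name)
            cols.append(x)
            names.append(term_label(term))
    if not cols:
        raise ConfigurationError("empty term list")
    X = np.column_stack(cols)
    return X, names, constants_used
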