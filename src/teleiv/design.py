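"""Regression design matrices with fixed reference levels.

Categorical covariates are one-hot encoded against fixed, documented
reference levels (treatment-effect estimates are invariant to this choice;
it only relabels the intercept).  Levels unseen in a supplied category map
collapse to the reference, with the affected row count returned to the
caller — the documented fallback when scoring data contains categories the
training data lacked.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["REFERENCE_LEVELS", "make_design", "DesignInfo"]

#: Reference level per categorical covariate.
REFERENCE_LEVELS = {
    "age_band": "<45",
    "sex": "Female",
    "race_ethnicity": "White",
    "insurance": "Private",
    "preferred_language": "English",
    "interpreter_needed": "No",
    "fellow_present": "No",
    "year": None,        # earliest year observed
    "diagnosis_group": None,  # first group alphabetically
}

_COVARIATE_ORDER = [
    "age_band",
    "race_ethnicity",
    "preferred_language",
    "insurance",
    "interpreter_needed",
    "fellow_present",
]


class DesignInfo:
    """A built design: matrix, column names, and the category map used."""

    def __init__(self, X, names, categories, n_unseen=0):
        self.X = X
        self.names = list(names)
        self.categories = categories
        self.n_unseen = n_unseen


def _levels(df, col, categories):
    if categories is not None and col in categories:
        return list(categories[col])
    ref = REFERENCE_LEVELS.get(col)
    seen = sorted(pd.unique(df[col].astype(str)))
    if ref is None:
        return seen
    return [ref] + [l for l in seen if l != ref]


def _dummies(df, col, levels):
    """Columns for all non-reference levels; unseen values -> all zeros."""
    vals = df[col].astype(str).to_numpy()
    unseen = int((~np.isin(vals, levels)).sum())
    cols, names = [], []
    for lev in levels[1:]:
        cols.append((vals == lev).astype(float))
        names.append(f"{col}[{lev}]")
    return cols, names, unseen


def make_design(
    df: pd.DataFrame,
    covariates: bool = True,
    diagnosis_fe: bool = False,
    include_sex: bool = False,
    year_fe: bool = True,
    categories: dict | None = None,
) -> DesignInfo:
    """Build the exogenous design matrix (always includes an intercept).

    With ``covariates=True`` the adjustment set is: age band, race/ethnicity,
    preferred language, insurance, interpreter need, fellow present,
    log distance, and (if ``year_fe``) calendar-year fixed effects.  Sex is
    off by default and restored by ``include_sex``.  ``diagnosis_fe`` adds
    diagnosis-group fixed effects.  Pass ``categories`` (from a previous
    :class:`DesignInfo`) to score new data against training levels; unseen
    levels map to the reference and are counted in ``n_unseen``.
    """
    n = len(df)
    cols = [np.ones(n)]
    names = ["const"]
    cats: dict[str, list] = {}
    unseen_total = 0

    def add_cat(col):
        nonlocal unseen_total
        levels = _levels(df, col, categories)
        cats[col] = levels
        c, nm, unseen = _dummies(df, col, levels)
        cols.extend(c)
        names.extend(nm)
        unseen_total += unseen

    if covariates:
        order = list(_COVARIATE_ORDER)
        if include_sex:
            order.insert(1, "sex")
        for col in order:
            add_cat(col)
        cols.append(pd.to_numeric(df["log_distance"]).to_numpy(dtype=float))
        names.append("log_distance")
        if year_fe:
            add_cat("year")
    if diagnosis_fe:
        add_cat("diagnosis_group")

    X = np.column_stack(cols) if n else np.empty((0, len(names)))
    return DesignInfo(X, names, cats, unseen_total)
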