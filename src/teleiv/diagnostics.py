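"""Instrument-validity falsification tests.

Two operational diagnostics for the clinician-preference instrument:

* **exclusion test** — clinicians' diagnosis-specific average follow-up rates
  in the prepandemic era (when there was no telemedicine) are regressed on
  their study-period telemedicine fraction, controlling for diagnosis group.
  A significant association would mean clinician telemedicine preference is
  tied to baseline follow-up scheduling style, breaking the exclusion
  restriction.

* **independence test** — a prepandemic linear model predicts follow-up
  counts from patient characteristics; predictions for the study cohort are
  averaged over each clinician's patient panel and regressed on the
  telemedicine fraction.  A significant association would mean patients with
  higher expected utilization sort toward high- or low-telemedicine
  clinicians.  Sorting on purely latent severity that leaves no trace in the
  observed covariates is invisible to this test, by construction.

Both regressions use one unweighted row per clinician-diagnosis cell and HC1
robust standard errors, with p-values from the normal reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import make_design
from .iv import RobustOLS

__all__ = ["DiagnosticResult", "exclusion_test", "independence_test"]

logger = logging.getLogger(__name__)


class DegenerateRegressorError(ValueError):
    """The instrument column has no variance across clinicians."""


@dataclass
class DiagnosticResult:
    """The tele-fraction coefficient from a falsification regression."""

    coefficient: float
    se: float
    p_value: float
    n_units: int   # clinician-diagnosis cells
    test: str      # "exclusion" | "independence"


def _eligible_both_periods(pre_analytic, profiles, min_npv):
    pre_counts = pre_analytic.groupby("clinician_id").size()
    study_ok = set(profiles.loc[profiles["eligible"], "clinician_id"])
    pre_ok = set(pre_counts.index[pre_counts >= min_npv])
    return study_ok & pre_ok


def _cell_regression(cells: pd.DataFrame, depvar: str, test: str,
                     weight_by_n: bool) -> DiagnosticResult:
    z = cells["tele_fraction"].to_numpy(dtype=float)
    if np.ptp(z) == 0:
        raise DegenerateRegressorError(
            "telemedicine fractions are identical across clinicians"
        )
    di = make_design(cells, covariates=False, diagnosis_fe=True)
    X = np.column_stack([z, di.X])
    names = ["tele_fraction"] + di.names
    y = cells[depvar].to_numpy(dtype=float)
    if weight_by_n:
        w = np.sqrt(cells["n_cell"].to_numpy(dtype=float))
        res = RobustOLS(y * w, X * w[:, None], names).fit()
    else:
        res = RobustOLS(y, X, names).fit()
    i = names.index("tele_fraction")
    coef, se = float(res.params[i]), float(res.bse[i])
    p = float(2.0 * stats.norm.sf(abs(coef / se))) if se > 0 else float(coef == 0.0)
    return DiagnosticResult(coef, se, p, len(cells), test)


def exclusion_test(
    pre_analytic: pd.DataFrame,
    profiles: pd.DataFrame,
    min_npv: int = 10,
    weight_by_n: bool = False,
) -> DiagnosticResult:
    """Placebo-outcome regression probing the exclusion restriction.

    Units are clinician-diagnosis cells with at least one prepandemic NPV,
    restricted to clinicians with at least ``min_npv`` NPVs in each period.
    The dependent variable is the cell's mean prepandemic follow-up count;
    the regressor of interest is the clinician's study-period telemedicine
    fraction, with diagnosis-group fixed effects.
    """
    keep = _eligible_both_periods(pre_analytic, profiles, min_npv)
    if len(keep) < 2:
        raise ValueError("need >= 2 clinicians eligible in both periods")
    sub = pre_analytic.loc[pre_analytic["clinician_id"].isin(keep)]
    cells = (
        sub.groupby(["clinician_id", "diagnosis_group"])
        .agg(mean_followups=("outcome_count", "mean"), n_cell=("outcome_count", "size"))
        .reset_index()
        .merge(profiles[["clinician_id", "tele_fraction"]], on="clinician_id")
    )
    return _cell_regression(cells, "mean_followups", "exclusion", weight_by_n)


def independence_test(
    pre_analytic: pd.DataFrame,
    study_analytic: pd.DataFrame,
    profiles: pd.DataFrame,
    min_npv: int = 10,
    weight_by_n: bool = False,
) -> DiagnosticResult:
    """Predicted-utilization sorting test probing instrument independence.

    Stage A fits OLS of the follow-up count on patient covariates and
    diagnosis fixed effects in the prepandemic cohort.  Stage B scores every
    study-period record (covariate levels unseen prepandemic collapse to the
    reference, with the affected count logged).  Stage C averages the
    predictions over clinician-diagnosis panels; stage D regresses those
    panel means on the telemedicine fraction with diagnosis fixed effects.
    """
    train = make_design(pre_analytic, covariates=True, diagnosis_fe=True,
                        year_fe=False)
    res_a = RobustOLS(
        pre_analytic["outcome_count"].to_numpy(dtype=float), train.X, train.names
    ).fit()
    score = make_design(study_analytic, covariates=True, diagnosis_fe=True,
                        year_fe=False, categories=train.categories)
    if score.n_unseen:
        logger.warning(
            "independence test: %d study-period values at levels unseen "
            "prepandemic mapped to reference", score.n_unseen,
        )
    predicted = score.X @ res_a.params

    keep = _eligible_both_periods(pre_analytic, profiles, min_npv)
    if len(keep) < 2:
        raise ValueError("need >= 2 clinicians eligible in both periods")
    sub = study_analytic.assign(predicted=predicted)
    sub = sub.loc[sub["clinician_id"].isin(keep)]
    cells = (
        sub.groupby(["clinician_id", "diagnosis_group"])
        .agg(mean_predicted=("predicted", "mean"), n_cell=("predicted", "size"))
        .reset_index()
        .merge(profiles[["clinician_id", "tele_fraction"]], on="clinician_id")
    )
    return _cell_regression(cells, "mean_predicted", "independence", weight_by_n)
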