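"""Descriptive surfaces: baseline table, diagnosis-group table, rate matrix.

Percentages mirror print conventions: one decimal, half away from zero.
Group comparisons use Pearson chi-square without continuity correction for
categorical characteristics, a two-sample t test for age (pooled variance by
default, Welch on request), and the two-sided Wilcoxon rank-sum test with
normal approximation and tie correction for distance to clinic.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import DIAGNOSIS_GROUPS

__all__ = [
    "round_half_away",
    "pct",
    "baseline_table",
    "diagnosis_table",
    "followup_rate_matrix",
]

_BASELINE_CATEGORICALS = [
    ("sex", "Sex"),
    ("race_ethnicity", "Race or ethnicity"),
    ("insurance", "Insurance"),
    ("preferred_language", "Preferred language"),
    ("interpreter_needed", "Interpreter needed"),
    ("fellow_present", "Fellow present"),
]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (print convention), e.g. 0.25 -> 0.3."""
    if not np.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    d = Decimal(repr(abs(float(x)))).quantize(q, rounding=ROUND_HALF_UP)
    return float(-d if x < 0 else d)


def pct(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage share as printed: 100*n/d rounded half away from zero."""
    if denominator == 0:
        return float("nan")
    return round_half_away(100.0 * numerator / denominator, ndigits)


def _chi2_p(table: np.ndarray):
    if table.shape[0] < 2 or table.shape[1] < 2:
        return np.nan, "not_computable"
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        return np.nan, "not_computable"
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return p, "chi_square"


def baseline_table(analytic: pd.DataFrame, welch: bool = False) -> pd.DataFrame:
    """Baseline patient characteristics by NPV modality with group tests.

    Returns a long table with one row per characteristic level: overall,
    telemedicine and in-person counts and column percentages, plus the
    comparison p-value (attached to the characteristic's first row) and the
    test used.  Characteristics with a single observed level get a
    not-computable flag instead of a p-value.
    """
    tele = analytic.loc[analytic["treatment"] == 1]
    inp = analytic.loc[analytic["treatment"] == 0]
    if len(tele) == 0 or len(inp) == 0:
        raise ValueError("both treatment groups must be nonempty")
    n_all, n_t, n_i = len(analytic), len(tele), len(inp)
    rows = [
        {
            "characteristic": "Overall", "level": "",
            "overall_n": n_all, "overall_pct": 100.0,
            "tele_n": n_t, "tele_pct": pct(n_t, n_all),
            "inperson_n": n_i, "inperson_pct": pct(n_i, n_all),
            "p_value": np.nan, "test": "",
        }
    ]

    age_t = tele["age_years"].to_numpy(dtype=float)
    age_i = inp["age_years"].to_numpy(dtype=float)
    t_p = stats.ttest_ind(age_t, age_i, equal_var=not welch).pvalue
    rows.append(
        {
            "characteristic": "Age (years)", "level": "mean (SD)",
            "overall_n": round_half_away(analytic["age_years"].mean(), 2),
            "overall_pct": round_half_away(analytic["age_years"].std(ddof=1), 2),
            "tele_n": round_half_away(age_t.mean(), 2),
            "tele_pct": round_half_away(age_t.std(ddof=1), 2),
            "inperson_n": round_half_away(age_i.mean(), 2),
            "inperson_pct": round_half_away(age_i.std(ddof=1), 2),
            "p_value": t_p, "test": "welch_t" if welch else "student_t",
        }
    )

    for col, label in _BASELINE_CATEGORICALS:
        levels = sorted(analytic[col].astype(str).unique())
        table = np.array(
            [
                [(tele[col].astype(str) == lev).sum() for lev in levels],
                [(inp[col].astype(str) == lev).sum() for lev in levels],
            ]
        ).T
        p, test = _chi2_p(table)
        for j, lev in enumerate(levels):
            o = int(table[j].sum())
            rows.append(
                {
                    "characteristic": label, "level": lev,
                    "overall_n": o, "overall_pct": pct(o, n_all),
                    "tele_n": int(table[j, 0]), "tele_pct": pct(table[j, 0], n_t),
                    "inperson_n": int(table[j, 1]),
                    "inperson_pct": pct(table[j, 1], n_i),
                    "p_value": p if j == 0 else np.nan,
                    "test": test if j == 0 else "",
                }
            )

    d_t = tele["distance_miles"].to_numpy(dtype=float)
    d_i = inp["distance_miles"].to_numpy(dtype=float)
    if np.ptp(np.concatenate([d_t, d_i])) == 0:
        w_p, w_test = np.nan, "not_computable"
    else:
        w_p = stats.mannwhitneyu(
            d_t, d_i, alternative="two-sided", method="asymptotic"
        ).pvalue
        w_test = "wilcoxon_rank_sum"
    rows.append(
        {
            "characteristic": "Distance to clinic (miles)", "level": "median (IQR)",
            "overall_n": round_half_away(float(np.median(analytic["distance_miles"])), 2),
            "overall_pct": np.nan,
            "tele_n": round_half_away(float(np.median(d_t)), 2), "tele_pct": np.nan,
            "inperson_n": round_half_away(float(np.median(d_i)), 2),
            "inperson_pct": np.nan,
            "p_value": w_p, "test": w_test,
        }
    )
    return pd.DataFrame(rows)


def diagnosis_table(analytic: pd.DataFrame) -> pd.DataFrame:
    """Per diagnosis group: NPV count, telemedicine share, distinct clinicians.

    Groups from the canonical list that are absent from the cohort are
    retained as zero rows; an overall row is appended.
    """
    rows = []
    for g in DIAGNOSIS_GROUPS:
        sub = analytic.loc[analytic["diagnosis_group"] == g]
        n = len(sub)
        n_tele = int(sub["treatment"].sum()) if n else 0
        rows.append(
            {
                "diagnosis_group": g,
                "n_npv": n,
                "n_npv_tele": n_tele,
                "tele_pct": pct(n_tele, n) if n else 0.0,
                "n_clinicians": int(sub["clinician_id"].nunique()) if n else 0,
            }
        )
    rows.append(
        {
            "diagnosis_group": "overall",
            "n_npv": len(analytic),
            "n_npv_tele": int(analytic["treatment"].sum()),
            "tele_pct": pct(int(analytic["treatment"].sum()), len(analytic)),
            "n_clinicians": int(analytic["clinician_id"].nunique()),
        }
    )
    return pd.DataFrame(rows)


def _rates(sub: pd.DataFrame) -> dict:
    n = len(sub)
    if n == 0:
        return {"n_patients": 0, "rate_total": 0.0, "rate_tele_fu": 0.0,
                "rate_inperson_fu": 0.0}
    return {
        "n_patients": n,
        "rate_total": 100.0 * sub["outcome_count"].sum() / n,
        "rate_tele_fu": 100.0 * sub["fu_telemedicine"].sum() / n,
        "rate_inperson_fu": 100.0 * sub["fu_in_person"].sum() / n,
    }


def followup_rate_matrix(analytic: pd.DataFrame) -> pd.DataFrame:
    """Follow-up visits per 100 patients by diagnosis group and NPV modality.

    Each cell reports the total follow-up rate and its split by follow-up
    modality; rows for both NPV modalities and a pooled column, plus overall
    rows, are included.  By construction the telemedicine and in-person
    follow-up rates sum to the total rate.
    """
    rows = []
    strata = list(DIAGNOSIS_GROUPS) + ["overall"]
    for g in strata:
        base = analytic if g == "overall" else analytic.loc[
            analytic["diagnosis_group"] == g
        ]
        for label, sub in (
            ("all", base),
            ("telemedicine", base.loc[base["treatment"] == 1]),
            ("in_person", base.loc[base["treatment"] == 0]),
        ):
            rows.append(
                {"diagnosis_group": g, "npv_modality": label, **_rates(sub)}
            )
    return pd.DataFrame(rows)
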