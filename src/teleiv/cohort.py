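"""Cohort construction: from a raw visit log to the analytic dataset.

The raw input is a tidy visit log (one row per completed visit).  This module
selects each patient's index new patient visit (NPV) inside the study window,
counts their follow-up visits over the following six months (183 days), builds
the clinician-preference instrument (each clinician's telemedicine fraction of
qualifying NPVs), applies clinician eligibility rules, and engineers the
covariates used by the regression models.
"""

from __future__ import annotations

import logging
from datetime import date

import numpy as np
import pandas as pd

from .simulate import DIAGNOSIS_GROUPS

__all__ = [
    "VisitLogError",
    "LOG_COLUMNS",
    "MODALITIES",
    "VISIT_CLASSES",
    "FOLLOWUP_HORIZON_DAYS",
    "read_visit_log",
    "validate_visit_log",
    "classify_modality",
    "select_index_visits",
    "count_followups",
    "build_instrument",
    "engineer_covariates",
    "build_cohort",
]

logger = logging.getLogger(__name__)


class VisitLogError(ValueError):
    """A visit-log row violates the schema; carries row/column location."""

    def __init__(self, message, row=None, column=None):
        self.row = row
        self.column = column
        loc = ""
        if row is not None:
            loc = f" (row {row}" + (f", column {column!r})" if column else ")")
        super().__init__(message + loc)


#: Required visit-log columns, in canonical order.
LOG_COLUMNS = [
    "patient_id",
    "clinician_id",
    "visit_date",
    "visit_class",
    "modality",
    "diagnosis_group",
    "age_years",
    "sex",
    "race_ethnicity",
    "insurance",
    "preferred_language",
    "interpreter_needed",
    "fellow_present",
    "distance_miles",
]

MODALITIES = ("video", "phone", "in_person")
VISIT_CLASSES = ("new_patient", "return")

#: Six months after the index visit, as a day count: the half-open
#: interval (0, 183] days after the NPV.
FOLLOWUP_HORIZON_DAYS = 183

#: Minimum qualifying NPVs for a clinician to enter the analysis.
MIN_NPV_DEFAULT = 10

STUDY_START_DEFAULT = date(2020, 6, 1)
STUDY_END_DEFAULT = date(2023, 5, 31)

#: Index dates on/after this boundary belong to the later study period.
PERIOD_BOUNDARY = date(2022, 1, 1)

_COVARIATE_FIELDS = [
    "age_years",
    "sex",
    "race_ethnicity",
    "insurance",
    "preferred_language",
    "interpreter_needed",
    "fellow_present",
    "distance_miles",
]


def read_visit_log(path) -> pd.DataFrame:
    """Read a delimited visit log (comma or tab autodetected) and validate it."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep, dtype={"patient_id": str, "clinician_id": str})
    validate_visit_log(df)
    return df


def validate_visit_log(df: pd.DataFrame) -> None:
    """Check schema; raise :class:`VisitLogError` at the first violation."""
    for col in LOG_COLUMNS:
        if col not in df.columns:
            raise VisitLogError(f"missing column {col!r}", column=col)
    if len(df) == 0:
        return
    dates = pd.to_datetime(df["visit_date"], format="%Y-%m-%d", errors="coerce")
    if dates.isna().any():
        i = int(np.flatnonzero(dates.isna().to_numpy())[0])
        raise VisitLogError(
            f"unparseable ISO-8601 date {df['visit_date'].iloc[i]!r}",
            row=i,
            column="visit_date",
        )
    for col, allowed in (("visit_class", VISIT_CLASSES), ("modality", MODALITIES)):
        bad = ~df[col].isin(allowed)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise VisitLogError(
                f"invalid {col} value {df[col].iloc[i]!r}; expected one of {allowed}",
                row=i,
                column=col,
            )
    for col in ("age_years", "distance_miles"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.notna() & (vals < 0)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise VisitLogError(
                f"negative {col} value {df[col].iloc[i]!r}", row=i, column=col
            )


def classify_modality(modality):
    """Map a visit modality to the binary treatment: telemedicine = video or phone.

    Accepts a scalar or an array/Series; unknown strings raise
    :class:`VisitLogError` with the offending row index.
    """
    if np.isscalar(modality):
        if modality in ("video", "phone"):
            return 1
        if modality == "in_person":
            return 0
        raise VisitLogError(f"unknown modality {modality!r}", row=0, column="modality")
    arr = np.asarray(modality)
    bad = ~np.isin(arr, MODALITIES)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise VisitLogError(
            f"unknown modality {arr[i]!r}", row=i, column="modality"
        )
    return np.isin(arr, ("video", "phone")).astype(np.int64)


def _as_datetime(s):
    return pd.to_datetime(s, format="%Y-%m-%d")


def _qualifying_npvs(visits, start, end, whitelist):
    d = _as_datetime(visits["visit_date"])
    mask = (
        (visits["visit_class"] == "new_patient")
        & (d >= pd.Timestamp(start))
        & (d <= pd.Timestamp(end))
        & visits["diagnosis_group"].isin(whitelist)
    )
    out = visits.loc[mask].copy()
    out["visit_date"] = d[mask]
    return out


def select_index_visits(
    visits: pd.DataFrame,
    start: date = STUDY_START_DEFAULT,
    end: date = STUDY_END_DEFAULT,
    whitelist=DIAGNOSIS_GROUPS,
) -> pd.DataFrame:
    """Pick each patient's index NPV.

    Qualifying rows are new patient visits dated inside the closed window
    with a whitelisted diagnosis group; when a patient has several, the
    earliest is kept (date ties broken by clinician id, lexicographically).
    """
    if len(tuple(whitelist)) == 0:
        raise ValueError("diagnosis whitelist must be nonempty")
    q = _qualifying_npvs(visits, start, end, whitelist)
    if len(q) == 0:
        return q
    q = q.sort_values(["patient_id", "visit_date", "clinician_id"], kind="mergesort")
    return q.groupby("patient_id", as_index=False, sort=True).head(1).reset_index(
        drop=True
    )


def count_followups(index_row, visits: pd.DataFrame, horizon_days: int = FOLLOWUP_HORIZON_DAYS):
    """Count one patient's follow-up visits within the horizon.

    Counts visits of the same patient with any clinician in the log whose
    date lies in the half-open interval (index_date, index_date + horizon];
    same-day visits are excluded.  Returns
    ``(outcome_count, any_followup, {"telemedicine": m, "in_person": k})``.
    """
    pid = index_row["patient_id"]
    d0 = pd.Timestamp(index_row["visit_date"])
    rows = visits.loc[visits["patient_id"] == pid]
    d = _as_datetime(rows["visit_date"])
    mask = (d > d0) & (d <= d0 + pd.Timedelta(days=horizon_days))
    tele = classify_modality(rows.loc[mask, "modality"].to_numpy()) if mask.any() else np.array([], dtype=int)
    total = int(mask.sum())
    return (
        total,
        int(total >= 1),
        {"telemedicine": int(tele.sum()), "in_person": int(total - tele.sum())},
    )


def _count_followups_all(index_df, visits, horizon_days=FOLLOWUP_HORIZON_DAYS):
    """Vectorised follow-up counting for a whole index set."""
    v = visits[["patient_id", "visit_date", "modality"]].copy()
    v["visit_date"] = _as_datetime(v["visit_date"])
    v["is_tele"] = v["modality"].isin(("video", "phone")).astype(np.int64)
    idx = index_df[["patient_id", "visit_date"]].rename(
        columns={"visit_date": "index_date"}
    )
    idx["index_date"] = _as_datetime(idx["index_date"])
    m = v.merge(idx, on="patient_id", how="inner")
    keep = (m["visit_date"] > m["index_date"]) & (
        m["visit_date"] <= m["index_date"] + pd.Timedelta(days=horizon_days)
    )
    m = m.loc[keep]
    g = m.groupby("patient_id")
    agg = pd.DataFrame(
        {"outcome_count": g.size(), "fu_telemedicine": g["is_tele"].sum()}
    )
    out = index_df[["patient_id"]].merge(
        agg, left_on="patient_id", right_index=True, how="left"
    ).fillna(0)
    out["outcome_count"] = out["outcome_count"].astype(np.int64)
    out["fu_telemedicine"] = out["fu_telemedicine"].astype(np.int64)
    out["fu_in_person"] = out["outcome_count"] - out["fu_telemedicine"]
    out["any_followup"] = (out["outcome_count"] >= 1).astype(np.int64)
    return out.set_index(index_df.index)


def build_instrument(
    visits: pd.DataFrame,
    start: date = STUDY_START_DEFAULT,
    end: date = STUDY_END_DEFAULT,
    whitelist=DIAGNOSIS_GROUPS,
    min_npv: int = MIN_NPV_DEFAULT,
    exclude_clinicians=(),
) -> pd.DataFrame:
    """Per-clinician NPV counts and telemedicine fraction (the instrument).

    ``tele_fraction`` is the share of the clinician's qualifying NPVs in the
    window conducted by video or phone — a proxy for how much telemedicine
    the clinician keeps on their new-patient schedule.  Eligibility requires
    at least ``min_npv`` qualifying NPVs and absence from the exclusion list.
    Clinicians appearing in the log with zero qualifying NPVs get a profile
    with ``n_npv = 0`` and no division.
    """
    exclude = set(exclude_clinicians)
    q = _qualifying_npvs(visits, start, end, whitelist)
    all_ids = pd.Index(sorted(visits["clinician_id"].unique()), name="clinician_id")
    if len(q):
        tele = classify_modality(q["modality"].to_numpy())
        g = q.assign(is_tele=tele).groupby("clinician_id")
        prof = pd.DataFrame({"n_npv": g.size(), "n_npv_tele": g["is_tele"].sum()})
    else:
        prof = pd.DataFrame(columns=["n_npv", "n_npv_tele"], dtype=np.int64)
    prof = prof.reindex(all_ids, fill_value=0).reset_index()
    prof["n_npv"] = prof["n_npv"].astype(np.int64)
    prof["n_npv_tele"] = prof["n_npv_tele"].astype(np.int64)
    with np.errstate(invalid="ignore"):
        prof["tele_fraction"] = np.where(
            prof["n_npv"] > 0, prof["n_npv_tele"] / prof["n_npv"].replace(0, 1), np.nan
        )
    prof["eligible"] = (prof["n_npv"] >= min_npv) & ~prof["clinician_id"].isin(exclude)
    prof["excluded_reason"] = np.select(
        [prof["clinician_id"].isin(exclude), prof["n_npv"] < min_npv],
        ["exclusion_list", f"fewer_than_{min_npv}_npvs"],
        default="",
    )
    return prof


def _age_band(age: np.ndarray) -> np.ndarray:
    return np.select([age < 45, age < 65], ["<45", "45-64"], default=">=65")


def engineer_covariates(index_rows: pd.DataFrame) -> pd.DataFrame:
    """Engineer model covariates on the index rows.

    Age is binned into <45 / 45-64 / >=65 (lower edge inclusive),
    ``log_distance = ln(max(distance, 0.1))``, and calendar year and study
    period (2020-21 vs 2022-23) derive from the visit date.  Rows missing
    any covariate are dropped (complete-case rule) with per-field counts
    logged.
    """
    out = index_rows.copy()
    missing = out[_COVARIATE_FIELDS].isna()
    if missing.to_numpy().any():
        per_field = missing.sum()
        for fld, cnt in per_field[per_field > 0].items():
            logger.warning("dropping %d rows with missing %s (complete case)", cnt, fld)
        out = out.loc[~missing.any(axis=1)].copy()
    age = pd.to_numeric(out["age_years"]).to_numpy(dtype=float)
    out["age_band"] = _age_band(age)
    out["log_distance"] = np.log(
        np.maximum(pd.to_numeric(out["distance_miles"]).to_numpy(dtype=float), 0.1)
    )
    d = _as_datetime(out["visit_date"])
    out["year"] = d.dt.year.astype(str)
    out["period"] = np.where(
        d >= pd.Timestamp(PERIOD_BOUNDARY), "p2022_23", "p2020_21"
    )
    return out.reset_index(drop=True)


def build_cohort(
    visits: pd.DataFrame,
    start: date = STUDY_START_DEFAULT,
    end: date = STUDY_END_DEFAULT,
    whitelist=DIAGNOSIS_GROUPS,
    min_npv: int = MIN_NPV_DEFAULT,
    exclude_clinicians=(),
    loo_instrument: bool = False,
    validate: bool = True,
):
    """Full pipeline from raw visit log to analytic table.

    Returns ``(analytic, profiles)``.  The analytic table has one row per
    included index NPV with treatment, instrument, the 6-month follow-up
    outcome (total and by follow-up modality) and engineered covariates;
    rows of ineligible clinicians are dropped.  ``loo_instrument=True``
    replaces each record's instrument by the leave-one-out fraction
    (own visit removed from the clinician's numerator and denominator).
    """
    if validate:
        validate_visit_log(visits)
    index_rows = select_index_visits(visits, start, end, whitelist)
    logger.info("index NPVs selected: %d", len(index_rows))
    profiles = build_instrument(
        visits, start, end, whitelist, min_npv=min_npv,
        exclude_clinicians=exclude_clinicians,
    )
    if len(index_rows) == 0:
        return index_rows, profiles
    counts = _count_followups_all(index_rows, visits)
    analytic = pd.concat([index_rows, counts.drop(columns="patient_id")], axis=1)
    analytic["treatment"] = classify_modality(analytic["modality"].to_numpy())
    elig = profiles.loc[profiles["eligible"], ["clinician_id", "tele_fraction",
                                               "n_npv", "n_npv_tele"]]
    analytic = analytic.merge(elig, on="clinician_id", how="inner")
    logger.info("index NPVs with eligible clinicians: %d", len(analytic))
    if loo_instrument:
        denom = analytic["n_npv"] - 1
        analytic["instrument"] = np.where(
            denom > 0,
            (analytic["n_npv_tele"] - analytic["treatment"]) / denom.replace(0, 1),
            np.nan,
        )
    else:
        analytic["instrument"] = analytic["tele_fraction"]
    analytic = analytic.drop(columns=["n_npv", "n_npv_tele"])
    analytic = engineer_covariates(analytic)
    logger.info("analytic records after covariate completeness: %d", len(analytic))
    analytic = analytic.sort_values(
        ["patient_id"], kind="mergesort"
    ).reset_index(drop=True)
    return analytic, profiles
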