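"""Shared fixtures.

The replication studies (parameter recovery, diagnostic null calibration)
are expensive, so they are computed once per session and shared between the
module property tests and the acceptance suite.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest

import teleiv as tv
from teleiv.design import make_design
from teleiv.iv import RobustOLS

logging.disable(logging.WARNING)

# Replication-study sizes.
N_RECOVERY_REPS = 300
N_NULL_REPS = 400
N_POWER_REPS = 200
DIAG_SIZE = dict(n_clinicians=40, npv_per_clinician_mean=30.0)


def build_pair(cfg):
    """Generate both periods and build both cohorts."""
    visits, truth = tv.generate_study_log(cfg)
    analytic, profiles = tv.build_cohort(visits, validate=False)
    pre = tv.generate_prepandemic_log(cfg)
    pre_analytic, _ = tv.build_cohort(
        pre, cfg.pre_start, cfg.pre_end, validate=False
    )
    return analytic, profiles, pre_analytic, truth


@pytest.fixture(scope="session")
def default_cohort():
    """One realistically sized synthetic cohort (both periods)."""
    cfg = tv.SimulationConfig(seed=7)
    analytic, profiles, pre_analytic, truth = build_pair(cfg)
    return {
        "config": cfg,
        "analytic": analytic,
        "profiles": profiles,
        "pre_analytic": pre_analytic,
        "truth": truth,
    }


def _ols_treatment_estimate(sub):
    di = make_design(sub)
    X = np.column_stack([sub["treatment"].to_numpy(float), di.X])
    res = RobustOLS(
        sub["outcome_count"].to_numpy(float), X, ["treatment"] + di.names
    ).fit()
    return 100.0 * res.params[0]


@pytest.fixture(scope="session")
def recovery_study():
    """Parameter-recovery replication study.

    Gaussian-linear generator, 40 clinicians, ~4,000 patients, unit-strength
    confounding, and the symptomatic-positive / chronic-negative effect sign
    pattern.  For each replicate and diagnosis stratum: the 2SLS estimate
    with its CI and the covariate-adjusted OLS benchmark, against the true
    effect (per 100 patients).
    """
    rows = []
    for rep in range(N_RECOVERY_REPS):
        cfg = tv.recovery_config(seed=10_000 + rep)
        visits, truth = tv.generate_study_log(cfg)
        analytic, _ = tv.build_cohort(visits, validate=False)
        primary = tv.run_primary(analytic)
        for g, fr in primary.items():
            if g == "overall":
                continue
            sub = analytic.loc[analytic["diagnosis_group"] == g]
            rows.append(
                {
                    "rep": rep,
                    "stratum": g,
                    "truth": 100.0 * truth.effects_by_diagnosis[g],
                    "estimate": fr.estimate,
                    "ci_low": fr.ci_low,
                    "ci_high": fr.ci_high,
                    "first_stage_F": fr.first_stage_F,
                    "ols_estimate": _ols_treatment_estimate(sub),
                }
            )
    return pd.DataFrame(rows)


def _diag_pair(seed, **overrides):
    cfg = tv.SimulationConfig(seed=seed, **DIAG_SIZE, **overrides)
    return build_pair(cfg)


@pytest.fixture(scope="session")
def diagnostic_null_pvalues():
    """Both falsification tests under their null, many replicates."""
    pex, pind = [], []
    for rep in range(N_NULL_REPS):
        analytic, profiles, pre_analytic, _ = _diag_pair(20_000 + rep)
        pex.append(tv.exclusion_test(pre_analytic, profiles).p_value)
        pind.append(
            tv.independence_test(pre_analytic, analytic, profiles).p_value
        )
    return np.asarray(pex), np.asarray(pind)


@pytest.fixture(scope="session")
def diagnostic_power():
    """Rejection rates under the injected instrument-validity violations."""
    excl_hits, ind_hits = [], []
    for rep in range(N_POWER_REPS):
        analytic, profiles, pre_analytic, _ = _diag_pair(
            30_000 + rep, exclusion_violation=0.5
        )
        r = tv.exclusion_test(pre_analytic, profiles)
        excl_hits.append(r.p_value < 0.05 and r.coefficient < 0)
    for rep in range(N_POWER_REPS):
        analytic, profiles, pre_analytic, _ = _diag_pair(
            40_000 + rep, sorting_violation=1.0, severity_covariate_load=1.0
        )
        r = tv.independence_test(pre_analytic, analytic, profiles)
        ind_hits.append(r.p_value < 0.05 and r.coefficient < 0)
    return float(np.mean(excl_hits)), float(np.mean(ind_hits))


@pytest.fixture()
def eight_row_log():
    """Handcrafted 8-row visit log whose cohort outputs are hand-enumerable.

    Patient p1: index NPV 2020-06-10 (clinician A, video, dyslipidemia); a
    next-day in-person return; a second qualifying NPV on 2020-07-01 with
    clinician B (not the index, but it counts as a follow-up visit); video
    returns at +183 days (2020-12-10, counted) and +184 days (2020-12-11,
    not counted).  Patient p2: an NPV on 2020-05-31 (before the window), the
    index NPV 2020-06-20 (clinician C, in person, syncope), and a same-day
    return (not counted).  Hence outcomes: p1 -> 3 follow-ups (1 tele,
    2 in person); p2 -> 0.  Instrument fractions: A=1.0, B=0.0, C=0.0.
    """
    base = dict(
        age_years=50.0, sex="Female", race_ethnicity="White",
        insurance="Private", preferred_language="English",
        interpreter_needed="No", fellow_present="No", distance_miles=10.0,
    )
    rows = [
        dict(patient_id="p1", clinician_id="A", visit_date="2020-06-10",
             visit_class="new_patient", modality="video",
             diagnosis_group="dyslipidemia", **base),
        dict(patient_id="p1", clinician_id="A", visit_date="2020-06-11",
             visit_class="return", modality="in_person",
             diagnosis_group="dyslipidemia", **base),
        dict(patient_id="p1", clinician_id="B", visit_date="2020-07-01",
             visit_class="new_patient", modality="in_person",
             diagnosis_group="chest_pain", **base),
        dict(patient_id="p1", clinician_id="A", visit_date="2020-12-10",
             visit_class="return", modality="video",
             diagnosis_group="dyslipidemia", **base),
        dict(patient_id="p1", clinician_id="A", visit_date="2020-12-11",
             visit_class="return", modality="video",
             diagnosis_group="dyslipidemia", **base),
        dict(patient_id="p2", clinician_id="A", visit_date="2020-05-31",
             visit_class="new_patient", modality="video",
             diagnosis_group="hypertension", **base),
        dict(patient_id="p2", clinician_id="C", visit_date="2020-06-20",
             visit_class="new_patient", modality="in_person",
             diagnosis_group="syncope_or_dizziness", **base),
        dict(patient_id="p2", clinician_id="C", visit_date="2020-06-20",
             visit_class="return", modality="in_person",
             diagnosis_group="syncope_or_dizziness", **base),
    ]
    return pd.DataFrame(rows)
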