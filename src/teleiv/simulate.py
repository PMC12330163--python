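"""Synthetic outpatient cardiology visit-log generator.

Emulates the statistical structure a clinician-preference instrumental-variable
analysis assumes: ~40 clinicians whose telemedicine share of new patient visits
(NPVs) spans 0%-100%, patients assigned to clinicians essentially at random,
an unobserved severity confounder driving both visit modality and follow-up
utilization, per-diagnosis causal effects of telemedicine on 6-month follow-up
counts, and "sticky" follow-up modality.  Ground truth (clinician propensities,
latent severities, true effects) is returned in a sidecar object and never
written into the emitted visit table, so parameter recovery is testable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "DIAGNOSIS_GROUPS",
    "SimulationConfig",
    "SimulationTruth",
    "ConfigurationError",
    "generate_clinicians",
    "generate_study_log",
    "generate_prepandemic_log",
    "recovery_config",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


#: The ten diagnosis groups, in canonical order.
DIAGNOSIS_GROUPS = (
    "atrial_fibrillation_or_flutter",
    "chest_pain",
    "coronary_artery_disease",
    "dyslipidemia",
    "dyspnea",
    "heart_failure",
    "hypertension",
    "palpitations",
    "preoperative_evaluation",
    "syncope_or_dizziness",
)

# NPV counts per diagnosis group in the emulated practice (total 5528);
# weights are these counts normalised.
_DIAGNOSIS_COUNTS = {
    "atrial_fibrillation_or_flutter": 219,
    "chest_pain": 999,
    "coronary_artery_disease": 618,
    "dyslipidemia": 1187,
    "dyspnea": 333,
    "heart_failure": 229,
    "hypertension": 695,
    "palpitations": 886,
    "preoperative_evaluation": 106,
    "syncope_or_dizziness": 256,
}

_TOTAL = float(sum(_DIAGNOSIS_COUNTS.values()))


def _default_diagnosis_weights() -> dict[str, float]:
    return {k: v / _TOTAL for k, v in _DIAGNOSIS_COUNTS.items()}


def _default_effects() -> dict[str, float]:
    # Per-patient additive effect of a telemedicine NPV on the 6-month
    # follow-up count: positive for symptomatic complaints, negative for
    # chronic risk-factor conditions, null elsewhere.
    return {
        "atrial_fibrillation_or_flutter": 0.0,
        "chest_pain": 0.369,
        "coronary_artery_disease": -0.295,
        "dyslipidemia": -0.245,
        "dyspnea": 0.370,
        "heart_failure": 0.0,
        "hypertension": 0.0,
        "palpitations": 0.349,
        "preoperative_evaluation": 0.0,
        "syncope_or_dizziness": 0.298,
    }


def _default_baselines() -> dict[str, float]:
    # Mean 6-month follow-up count under in-person evaluation.  Chosen so the
    # cohort-wide rate lands near 57 visits per 100 patients, with heart
    # failure highest (~105/100) and preoperative evaluation lowest (~26/100).
    return {
        "atrial_fibrillation_or_flutter": 0.75,
        "chest_pain": 0.45,
        "coronary_artery_disease": 0.70,
        "dyslipidemia": 0.50,
        "dyspnea": 0.65,
        "heart_failure": 1.05,
        "hypertension": 0.50,
        "palpitations": 0.40,
        "preoperative_evaluation": 0.26,
        "syncope_or_dizziness": 0.45,
    }


def _default_covariate_marginals() -> dict:
    # Category probabilities emulating the overall column of the emulated
    # practice's baseline table; age ~ N(56, 17.5^2) clipped to [18, 95];
    # distance to clinic lognormal with median ~17.8 miles.
    return {
        "sex": {"Female": 0.542, "Male": 0.458},
        "race_ethnicity": {
            "Asian": 0.247,
            "American Indian or Alaska Native": 0.002,
            "Black or African American": 0.030,
            "Hispanic or Latino": 0.138,
            "Native Hawaiian or Pacific Islander": 0.010,
            "White": 0.432,
            "Unknown": 0.141,
        },
        "insurance": {
            "Private": 0.449,
            "Medicare": 0.344,
            "Medicaid": 0.132,
            "Other": 0.075,
        },
        "preferred_language": {
            "English": 0.863,
            "Spanish": 0.039,
            "Mandarin": 0.025,
            "Other": 0.073,
        },
        "interpreter_needed": {"Yes": 0.106, "No": 0.894},
        "fellow_present": {"Yes": 0.30, "No": 0.70},
        "age_mean": 56.0,
        "age_sd": 17.5,
        "distance_log_mean": 2.879,  # ln(17.8)
        "distance_log_sd": 0.90,
    }


def _default_covariate_effects() -> dict[str, float]:
    # Small, deliberately arbitrary outcome effects of observed covariates.
    return {
        "age_per_decade": 0.02,
        "female": 0.0,
        "medicaid": 0.05,
        "interpreter": 0.03,
        "log_distance": -0.02,
        "fellow": 0.02,
    }


# Fixed, small covariate terms in the treatment (modality) log-odds: younger
# and privately insured patients are somewhat likelier to take telemedicine.
# Centered so they shift composition, not the overall telemedicine share.
_TREAT_AGE_Z = -0.25
_TREAT_PRIVATE = 0.30
_PRIVATE_SHARE = 0.449
# Share of telemedicine visits done by video rather than phone (~2814/2959).
_VIDEO_SHARE = 0.951


@dataclass
class SimulationConfig:
    """All knobs of the synthetic visit-log generator.

    The defaults reproduce the marginal structure of the emulated practice:
    40 clinicians, ~5,500 NPVs over three years, the diagnosis-group mix and
    covariate marginals above, unit-strength confounding through a latent
    severity, and sticky follow-up modality (83.6% / 44.4%).
    """

    n_clinicians: int = 40
    npv_per_clinician_mean: float = 138.2
    diagnosis_weights: dict = field(default_factory=_default_diagnosis_weights)
    propensity_dist: dict = field(
        default_factory=lambda: {"dist": "beta", "a": 0.60, "b": 0.52}
    )
    covariate_marginals: dict = field(default_factory=_default_covariate_marginals)
    confound_treat: float = 0.5     # gamma: severity -> modality log-odds
    confound_outcome: float = 0.5   # delta: severity -> outcome location
    effects_by_diagnosis: dict = field(default_factory=_default_effects)
    baselines_by_diagnosis: dict = field(default_factory=_default_baselines)
    covariate_effects: dict = field(default_factory=_default_covariate_effects)
    outcome_family: str = "truncated_poisson"  # or "gaussian_linear"
    outcome_sd: float = 0.75        # gaussian_linear residual sd
    sorting_violation: float = 0.0  # severity-propensity sorting strength
    severity_covariate_load: float = 0.0  # corr(severity, observed age)
    exclusion_violation: float = 0.0  # low-propensity clinicians' extra follow-ups
    sticky_prob_tele: float = 0.836
    sticky_prob_inperson: float = 0.444
    study_start: date = date(2020, 6, 1)
    study_end: date = date(2023, 5, 31)
    pre_start: date = date(2017, 1, 1)
    pre_end: date = date(2019, 8, 31)
    seed: int = 0

    def validate(self) -> None:
        if self.n_clinicians < 2:
            raise ConfigurationError(
                "n_clinicians must be >= 2; a single clinician makes the "
                "preference instrument degenerate"
            )
        w = np.array([self.diagnosis_weights[g] for g in DIAGNOSIS_GROUPS])
        if abs(w.sum() - 1.0) > 1e-12 or (w < 0).any() or (w > 1).any():
            raise ConfigurationError("diagnosis_weights must be a probability vector")
        for name in ("effects_by_diagnosis", "baselines_by_diagnosis"):
            d = getattr(self, name)
            missing = set(DIAGNOSIS_GROUPS) - set(d)
            if missing:
                raise ConfigurationError(f"{name} missing groups: {sorted(missing)}")
        if any(v < 0 for v in self.baselines_by_diagnosis.values()):
            raise ConfigurationError("baselines_by_diagnosis must be nonnegative")
        for p in (self.sticky_prob_tele, self.sticky_prob_inperson):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("sticky probabilities must lie in [0, 1]")
        if not -1.0 <= self.severity_covariate_load <= 1.0:
            raise ConfigurationError("severity_covariate_load must lie in [-1, 1]")
        if self.outcome_family not in ("gaussian_linear", "truncated_poisson"):
            raise ConfigurationError(f"unknown outcome_family {self.outcome_family!r}")
        if not (self.study_start <= self.study_end and self.pre_start <= self.pre_end):
            raise ConfigurationError("window start must not follow window end")
        if self.pre_end >= self.study_start:
            raise ConfigurationError("prepandemic and study windows must not overlap")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SimulationTruth:
    """Generator ground truth, kept apart from the emitted visit table."""

    clinicians: pd.DataFrame       # clinician_id, propensity
    patients: pd.DataFrame         # patient_id, clinician_id, severity, treatment, mu
    effects_by_diagnosis: dict
    confound_treat: float
    confound_outcome: float

    def save(self, directory) -> None:
        """Write the sidecar as plain-text tables plus a key=value file."""
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.clinicians.to_csv(d / "truth_clinicians.csv", index=False)
        self.patients.to_csv(d / "truth_patients.csv", index=False)
        with open(d / "truth_params.txt", "w") as fh:
            fh.write(f"confound_treat={self.confound_treat}\n")
            fh.write(f"confound_outcome={self.confound_outcome}\n")
            for g in DIAGNOSIS_GROUPS:
                fh.write(f"effect.{g}={self.effects_by_diagnosis[g]}\n")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def generate_clinicians(config: SimulationConfig) -> pd.DataFrame:
    """Draw per-clinician telemedicine propensities pi_j on [0, 1].

    With the default (bathtub-shaped beta) distribution the realized
    propensities of 40 clinicians span essentially the full unit interval,
    emulating practices whose clinicians range from never to always using
    telemedicine for new patients.
    """
    config.validate()
    rng = _rng(config, 0)
    dist = config.propensity_dist
    kind = dist.get("dist", "beta")
    if kind == "beta":
        pi = rng.beta(dist["a"], dist["b"], size=config.n_clinicians)
    elif kind == "fixed":
        pi = np.full(config.n_clinicians, float(dist["value"]))
    else:
        raise ConfigurationError(f"unknown propensity_dist {kind!r}")
    if ((pi < 0) | (pi > 1)).any():
        raise ConfigurationError("propensities outside [0, 1]")
    ids = [f"C{j + 1:03d}" for j in range(config.n_clinicians)]
    return pd.DataFrame({"clinician_id": ids, "propensity": pi})


def _draw_covariates(rng, n, marg, severity, load):
    """Patient covariates; age optionally loads on latent severity."""
    eps = rng.standard_normal(n)
    age = marg["age_mean"] + marg["age_sd"] * (
        np.sqrt(max(0.0, 1.0 - load**2)) * eps + load * severity
    )
    age = np.clip(age, 18.0, 95.0).round(1)

    def cat(name):
        levels = list(marg[name].keys())
        p = np.array(list(marg[name].values()), dtype=float)
        p = p / p.sum()
        return rng.choice(levels, size=n, p=p)

    distance = np.exp(
        rng.normal(marg["distance_log_mean"], marg["distance_log_sd"], size=n)
    ).round(2)
    return pd.DataFrame(
        {
            "age_years": age,
            "sex": cat("sex"),
            "race_ethnicity": cat("race_ethnicity"),
            "insurance": cat("insurance"),
            "preferred_language": cat("preferred_language"),
            "interpreter_needed": cat("interpreter_needed"),
            "fellow_present": cat("fellow_present"),
            "distance_miles": distance,
        }
    )


def _covariate_outcome_term(cov: pd.DataFrame, theta: dict, age_mean: float):
    x = np.zeros(len(cov))
    x += theta.get("age_per_decade", 0.0) * (cov["age_years"].to_numpy() - age_mean) / 10.0
    x += theta.get("female", 0.0) * (cov["sex"].to_numpy() == "Female")
    x += theta.get("medicaid", 0.0) * (cov["insurance"].to_numpy() == "Medicaid")
    x += theta.get("interpreter", 0.0) * (cov["interpreter_needed"].to_numpy() == "Yes")
    x += theta.get("log_distance", 0.0) * np.log(
        np.maximum(cov["distance_miles"].to_numpy(), 0.1)
    )
    x += theta.get("fellow", 0.0) * (cov["fellow_present"].to_numpy() == "Yes")
    return x


def _assign_clinicians(rng, severity, pi, sorting):
    """Uniform assignment, or severity-tilted when sorting != 0.

    With sorting > 0, higher-severity patients are tilted toward clinicians
    with below-average telemedicine propensity (softmax weights in
    -sorting * severity_i * z(pi_j)).
    """
    n, j = len(severity), len(pi)
    if sorting == 0.0:
        return rng.integers(0, j, size=n)
    z = (pi - pi.mean()) / (pi.std() if pi.std() > 0 else 1.0)
    logits = -sorting * severity[:, None] * z[None, :]
    logits -= logits.max(axis=1, keepdims=True)
    w = np.exp(logits)
    w /= w.sum(axis=1, keepdims=True)
    u = rng.random(n)
    return (w.cumsum(axis=1) < u[:, None]).sum(axis=1)


def _uniform_dates(rng, n, start: date, end: date):
    span = (end - start).days
    offs = rng.integers(0, span + 1, size=n)
    base = pd.Timestamp(start)
    return base + pd.to_timedelta(offs, unit="D")


def _counts_from_location(rng, mu, family, sd):
    """Nonnegative integer follow-up counts with (near-)linear mean mu.

    truncated_poisson: Poisson(max(0.01, mu)).  gaussian_linear: the real
    outcome mu + N(0, sd^2) is floored at zero and stochastically rounded,
    which preserves the conditional mean exactly wherever the real outcome
    is nonnegative.
    """
    if family == "truncated_poisson":
        return rng.poisson(np.maximum(0.01, mu))
    y = mu + sd * rng.standard_normal(len(mu))
    y = np.maximum(0.0, y)
    lo = np.floor(y)
    return (lo + (rng.random(len(y)) < (y - lo))).astype(np.int64)


_LOG_COLUMNS = [
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


def _empty_log() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in _LOG_COLUMNS})


def _emit_followups(rng, index_rows: pd.DataFrame, counts, sticky_p, horizon=183):
    """One dated return-visit row per follow-up, modality by a sticky coin."""
    rep = np.repeat(np.arange(len(index_rows)), counts)
    if len(rep) == 0:
        return _empty_log()
    fu = index_rows.iloc[rep].copy().reset_index(drop=True)
    offsets = rng.integers(1, horizon + 1, size=len(rep))
    fu["visit_date"] = pd.to_datetime(fu["visit_date"]) + pd.to_timedelta(
        offsets, unit="D"
    )
    fu["visit_class"] = "return"
    tele = rng.random(len(rep)) < np.repeat(sticky_p, counts)
    video = rng.random(len(rep)) < _VIDEO_SHARE
    fu["modality"] = np.where(tele, np.where(video, "video", "phone"), "in_person")
    return fu


def _build_period_log(config, rng, clinicians, period, id_prefix):
    """Shared machinery for the study and prepandemic logs."""
    n = int(round(config.n_clinicians * config.npv_per_clinician_mean))
    if n == 0:
        truth_pat = pd.DataFrame(
            columns=["patient_id", "clinician_id", "severity", "treatment", "mu"]
        )
        return _empty_log(), truth_pat

    marg = config.covariate_marginals
    severity = rng.standard_normal(n)
    cov = _draw_covariates(rng, n, marg, severity, config.severity_covariate_load)
    dx = rng.choice(
        DIAGNOSIS_GROUPS,
        size=n,
        p=np.array([config.diagnosis_weights[g] for g in DIAGNOSIS_GROUPS]),
    )
    pi = clinicians["propensity"].to_numpy()
    assign = _assign_clinicians(rng, severity, pi, config.sorting_violation)
    clin_ids = clinicians["clinician_id"].to_numpy()[assign]
    pi_i = pi[assign]

    if period == "study":
        start, end = config.study_start, config.study_end
        zage = (cov["age_years"].to_numpy() - marg["age_mean"]) / marg["age_sd"]
        eta = (
            np.log(np.clip(pi_i, 1e-9, 1 - 1e-9) / np.clip(1 - pi_i, 1e-9, 1 - 1e-9))
            + config.confound_treat * severity
            + _TREAT_AGE_Z * zage
            + _TREAT_PRIVATE
            * ((cov["insurance"].to_numpy() == "Private") - _PRIVATE_SHARE)
        )
        treat = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(np.int64)
        # Degenerate propensities are honored exactly.
        treat = np.where(pi_i <= 0.0, 0, np.where(pi_i >= 1.0, 1, treat))
    else:
        start, end = config.pre_start, config.pre_end
        treat = np.zeros(n, dtype=np.int64)

    alpha = np.array([config.baselines_by_diagnosis[g] for g in dx])
    beta = np.array([config.effects_by_diagnosis[g] for g in dx])
    mu = (
        alpha
        + beta * treat
        + _covariate_outcome_term(cov, config.covariate_effects, marg["age_mean"])
        + config.confound_outcome * severity
        + config.exclusion_violation * (1.0 - pi_i)
    )
    counts = _counts_from_location(rng, mu, config.outcome_family, config.outcome_sd)

    video = rng.random(n) < _VIDEO_SHARE
    modality = np.where(
        treat == 1, np.where(video, "video", "phone"), "in_person"
    )
    index_rows = pd.DataFrame(
        {
            "patient_id": [f"{id_prefix}{i + 1:06d}" for i in range(n)],
            "clinician_id": clin_ids,
            "visit_date": _uniform_dates(rng, n, start, end),
            "visit_class": "new_patient",
            "modality": modality,
            "diagnosis_group": dx,
        }
    )
    index_rows = pd.concat([index_rows, cov], axis=1)[_LOG_COLUMNS]

    if period == "study":
        sticky = np.where(treat == 1, config.sticky_prob_tele, config.sticky_prob_inperson)
    else:
        sticky = np.zeros(n)  # prepandemic follow-ups are all in person
    followups = _emit_followups(rng, index_rows, counts, sticky)

    log = pd.concat([index_rows, followups], ignore_index=True)
    log = log.sort_values(
        ["visit_date", "patient_id", "visit_class"], kind="mergesort"
    ).reset_index(drop=True)
    log["visit_date"] = pd.to_datetime(log["visit_date"]).dt.strftime("%Y-%m-%d")

    truth_pat = pd.DataFrame(
        {
            "patient_id": index_rows["patient_id"],
            "clinician_id": clin_ids,
            "severity": severity,
            "treatment": treat,
            "mu": mu,
        }
    )
    return log, truth_pat


def generate_study_log(config: SimulationConfig):
    """Generate the study-period visit log and its ground-truth sidecar.

    Returns ``(visits, truth)`` where ``visits`` is a tidy table with one row
    per completed visit (index NPVs plus dated follow-up rows) and ``truth``
    is a :class:`SimulationTruth`.  Identical config and seed give
    byte-identical tables.
    """
    config.validate()
    clinicians = generate_clinicians(config)
    rng = _rng(config, 1)
    log, truth_pat = _build_period_log(config, rng, clinicians, "study", "P")
    truth = SimulationTruth(
        clinicians=clinicians,
        patients=truth_pat,
        effects_by_diagnosis=dict(config.effects_by_diagnosis),
        confound_treat=config.confound_treat,
        confound_outcome=config.confound_outcome,
    )
    return log, truth


def generate_prepandemic_log(config: SimulationConfig) -> pd.DataFrame:
    """Generate the prepandemic visit log: same clinicians, no telemedicine.

    Outcomes follow the same baseline/covariate/severity structure with
    treatment fixed at zero, so per-clinician placebo regressions against the
    study-period instrument are computable and null by construction (unless
    ``exclusion_violation`` is set).
    """
    config.validate()
    clinicians = generate_clinicians(config)
    rng = _rng(config, 2)
    log, _ = _build_period_log(config, rng, clinicians, "pre", "Q")
    return log


def recovery_config(**overrides) -> SimulationConfig:
    """Preset for linear parameter-recovery studies.

    Gaussian outcome family with raised baselines (alpha_d = 4.0) so that
    negative latent outcomes — which the nonnegative visit-count emission
    would truncate — occur for well under 1% of patients even with
    unit-strength confounding; the linear IV estimand then equals the true
    per-diagnosis effect to within simulation error.
    """
    cfg = SimulationConfig(
        npv_per_clinician_mean=100.0,
        outcome_family="gaussian_linear",
        outcome_sd=0.75,
        baselines_by_diagnosis={g: 4.0 for g in DIAGNOSIS_GROUPS},
        confound_treat=1.0,
        confound_outcome=1.0,
    )
    return cfg.replace(**overrides)
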