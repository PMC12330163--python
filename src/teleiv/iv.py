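"""Just-identified two-stage least squares and OLS with sandwich inference.

These estimators are written from first principles (dense linear algebra
only): ordinary least squares with an HC1 heteroskedasticity-robust
covariance, and two-stage least squares (2SLS) in which the endogenous
treatment is first regressed on the instrument(s) and exogenous covariates,
the outcome is then regressed on the fitted treatment and covariates, and
the reported robust covariance is the HC1 sandwich built from *structural*
residuals (actual treatment, not fitted).  Confidence intervals use the
normal critical value 1.959964.

The high-level drivers reproduce the study's model battery: one 2SLS per
diagnosis group plus a pooled model with diagnosis fixed effects
(:func:`run_primary`), and the sensitivity set — linear-probability 2SLS on
the any-follow-up indicator, covariate-free models, and a period-interaction
model with two endogenous terms (:func:`run_sensitivities`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .design import make_design
from .simulate import DIAGNOSIS_GROUPS

__all__ = [
    "Z_CRIT",
    "SingularDesignError",
    "WeakInstrumentError",
    "DegenerateOutcomeError",
    "RobustOLS",
    "TwoStageLS",
    "RegressionResults",
    "IVResults",
    "ModelSpec",
    "FitResult",
    "fit_ols",
    "fit_2sls",
    "run_primary",
    "run_sensitivities",
]

logger = logging.getLogger(__name__)

#: Two-sided 95% normal critical value.
Z_CRIT = 1.959964


class SingularDesignError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; names the collinear columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"singular design; collinear columns: {self.columns}")


class WeakInstrumentError(ValueError):
    """Instrument has (numerically) no variance after partialling covariates."""


class DegenerateOutcomeError(ValueError):
    """Outcome has zero variance; the model is not estimable."""


def _check_rank(X: np.ndarray, names) -> None:
    n, k = X.shape
    if n <= k:
        raise SingularDesignError(list(names))
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(n, k) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int((diag > tol).sum())
    if rank < k:
        raise SingularDesignError([names[j] for j in piv[rank:]])


def _sandwich(bread_X: np.ndarray, resid: np.ndarray, cluster=None) -> np.ndarray:
    """HC1 (or CR1 cluster-robust) covariance around the given bread matrix."""
    n, k = bread_X.shape
    xtx_inv = np.linalg.inv(bread_X.T @ bread_X)
    if cluster is None:
        xe = bread_X * resid[:, None]
        meat = xe.T @ xe
        factor = n / (n - k)
    else:
        codes, _ = pd.factorize(np.asarray(cluster))
        g = codes.max() + 1
        xe = bread_X * resid[:, None]
        sums = np.zeros((g, k))
        np.add.at(sums, codes, xe)
        meat = sums.T @ sums
        factor = (g / (g - 1)) * ((n - 1) / (n - k))
    return factor * (xtx_inv @ meat @ xtx_inv)


class RegressionResults:
    """Coefficients with a robust covariance; statsmodels-flavoured surface."""

    def __init__(self, params, cov_params, names, nobs, df_resid, resid,
                 fittedvalues, estimator="ols"):
        self.params = np.asarray(params)
        self.cov_params = np.asarray(cov_params)
        self.names = list(names)
        self.nobs = int(nobs)
        self.df_resid = int(df_resid)
        self.resid = resid
        self.fittedvalues = fittedvalues
        self.estimator = estimator

    @property
    def bse(self):
        return np.sqrt(np.diag(self.cov_params))

    @property
    def tvalues(self):
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self):
        return 2.0 * stats.norm.sf(np.abs(self.tvalues))

    def conf_int(self, alpha: float = 0.05):
        z = stats.norm.ppf(1 - alpha / 2) if alpha != 0.05 else Z_CRIT
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return np.column_stack([lo, hi])

    def summary(self) -> str:
        ci = self.conf_int()
        rows = [
            f"{self.estimator.upper()} results  (n={self.nobs}, robust HC-type SEs)",
            f"{'':24s}{'coef':>12s}{'robust se':>12s}{'z':>9s}"
            f"{'P>|z|':>9s}{'[0.025':>12s}{'0.975]':>12s}",
        ]
        for i, name in enumerate(self.names):
            rows.append(
                f"{name:24s}{self.params[i]:12.4f}{self.bse[i]:12.4f}"
                f"{self.tvalues[i]:9.2f}{self.pvalues[i]:9.3f}"
                f"{ci[i, 0]:12.4f}{ci[i, 1]:12.4f}"
            )
        return "\n".join(rows)

    def __getitem__(self, name: str) -> float:
        return float(self.params[self.names.index(name)])


class IVResults(RegressionResults):
    """2SLS results; adds first-stage strength diagnostics."""

    def __init__(self, *args, first_stage_F=None, first_stage=None, **kw):
        super().__init__(*args, estimator="tsls", **kw)
        self.first_stage_F = first_stage_F
        self.first_stage = first_stage


class RobustOLS:
    """OLS of ``y`` on ``X`` with heteroskedasticity-robust (HC1) inference.

    The confounded benchmark of the IV analysis and the workhorse behind the
    falsification diagnostics and the first stage.
    """

    def __init__(self, y, X, names=None):
        self.y = np.asarray(y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.X.shape[0] != self.y.shape[0]:
            self.X = self.X.T
        self.names = list(names) if names is not None else [
            f"x{i}" for i in range(self.X.shape[1])
        ]

    def fit(self, robust: bool = True, cluster=None) -> RegressionResults:
        y, X = self.y, self.X
        n, k = X.shape
        _check_rank(X, self.names)
        params, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted = X @ params
        resid = y - fitted
        if robust:
            cov = _sandwich(X, resid, cluster=cluster)
        else:
            sigma2 = resid @ resid / (n - k)
            cov = sigma2 * np.linalg.inv(X.T @ X)
        return RegressionResults(params, cov, self.names, n, n - k, resid, fitted)


def _robust_wald_F(res: RegressionResults, idx) -> float:
    """Robust Wald statistic (divided by q) for the coefficients in idx."""
    idx = np.asarray(idx)
    b = res.params[idx]
    v = res.cov_params[np.ix_(idx, idx)]
    return float(b @ np.linalg.solve(v, b) / len(idx))


class TwoStageLS:
    """Just-identified two-stage least squares.

    Stage 1 regresses each endogenous column on [instruments, exogenous
    covariates]; stage 2 regresses the outcome on [fitted endogenous,
    covariates].  Robust covariance: HC1 sandwich around the second-stage
    bread, with structural residuals ``y - endog @ b_endog - exog @ b_exog``.
    ``first_stage_F`` is the robust Wald statistic on the instrument
    coefficients in the (weakest) first stage.
    """

    def __init__(self, y, endog, instruments, exog, endog_names=None,
                 exog_names=None, instrument_names=None):
        self.y = np.asarray(y, dtype=float).ravel()
        self.endog = np.column_stack([np.asarray(endog, dtype=float)]) \
            if np.asarray(endog).ndim == 1 else np.asarray(endog, dtype=float)
        self.instruments = np.column_stack([np.asarray(instruments, dtype=float)]) \
            if np.asarray(instruments).ndim == 1 else np.asarray(instruments, dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.y.shape[0]:
            self.exog = self.exog.T
        m = self.endog.shape[1]
        q = self.instruments.shape[1]
        self.endog_names = list(endog_names) if endog_names else [
            f"endog{i}" for i in range(m)
        ]
        self.exog_names = list(exog_names) if exog_names else [
            f"w{i}" for i in range(self.exog.shape[1])
        ]
        self.instrument_names = list(instrument_names) if instrument_names else [
            f"z{i}" for i in range(q)
        ]
        if q < m:
            raise ValueError("fewer instruments than endogenous regressors")

    def fit(self, cluster=None) -> IVResults:
        y, D, Z, W = self.y, self.endog, self.instruments, self.exog
        n = len(y)
        # Degenerate-instrument guard: each instrument must retain variance
        # after partialling out the exogenous covariates.
        Wpinv = np.linalg.pinv(W)
        Zres = Z - W @ (Wpinv @ Z)
        scale = np.abs(Z).max(axis=0)
        scale[scale == 0] = 1.0
        if np.any(np.sqrt((Zres**2).mean(axis=0)) / scale < 1e-10):
            raise WeakInstrumentError(
                "instrument is constant after partialling out covariates"
            )
        stage1_X = np.column_stack([Z, W])
        stage1_names = self.instrument_names + self.exog_names
        _check_rank(stage1_X, stage1_names)
        first_stage, fitted_D, fs_F = [], [], []
        zidx = np.arange(Z.shape[1])
        for j in range(D.shape[1]):
            res1 = RobustOLS(D[:, j], stage1_X, stage1_names).fit(cluster=cluster)
            first_stage.append(res1)
            fitted_D.append(res1.fittedvalues)
            fs_F.append(_robust_wald_F(res1, zidx))
        fitted_D = np.column_stack(fitted_D)
        X2 = np.column_stack([fitted_D, W])
        names = self.endog_names + self.exog_names
        _check_rank(X2, names)
        params, *_ = np.linalg.lstsq(X2, y, rcond=None)
        structural_X = np.column_stack([D, W])
        resid = y - structural_X @ params
        cov = _sandwich(X2, resid, cluster=cluster)
        k = X2.shape[1]
        return IVResults(
            params, cov, names, n, n - k,
            resid=resid, fittedvalues=structural_X @ params,
            first_stage_F=float(min(fs_F)), first_stage=first_stage,
        )


@dataclass
class ModelSpec:
    """What a single fitted model was: outcome, adjustment, stratum, scale."""

    outcome: str = "count"            # "count" | "any_followup"
    covariates_on: bool = True
    stratum: str = "overall"
    period_interaction: bool = False
    scale: float = 100.0


@dataclass
class FitResult:
    """A fitted treatment effect on the per-``scale``-patients scale."""

    estimate: float
    robust_se: float
    ci_low: float
    ci_high: float
    n_obs: int
    estimator: str
    spec: ModelSpec
    first_stage_F: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "stratum": self.spec.stratum,
            "outcome": self.spec.outcome,
            "covariates": self.spec.covariates_on,
            "interaction": self.spec.period_interaction,
            "estimator": self.estimator,
            "estimate": self.estimate,
            "robust_se": self.robust_se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_obs": self.n_obs,
            "first_stage_F": self.first_stage_F,
        }


def fit_ols(y, X, names=None, robust=True, cluster=None) -> RegressionResults:
    """OLS with HC1 sandwich errors (functional convenience wrapper)."""
    return RobustOLS(y, X, names).fit(robust=robust, cluster=cluster)


def fit_2sls(y, treatment, instrument, exog, exog_names=None,
             cluster=None) -> IVResults:
    """Single-endogenous-regressor 2SLS (functional convenience wrapper)."""
    model = TwoStageLS(
        y, treatment, instrument, exog,
        endog_names=["treatment"], instrument_names=["instrument"],
        exog_names=exog_names,
    )
    return model.fit(cluster=cluster)


def _result_from(res: RegressionResults, coef: str, spec: ModelSpec) -> FitResult:
    i = res.names.index(coef)
    est = res.params[i] * spec.scale
    se = res.bse[i] * spec.scale
    return FitResult(
        estimate=float(est),
        robust_se=float(se),
        ci_low=float(est - Z_CRIT * se),
        ci_high=float(est + Z_CRIT * se),
        n_obs=res.nobs,
        estimator=res.estimator,
        spec=spec,
        first_stage_F=getattr(res, "first_stage_F", None),
    )


def _strata(analytic: pd.DataFrame):
    groups = [g for g in DIAGNOSIS_GROUPS if g in set(analytic["diagnosis_group"])]
    return groups + ["overall"]


def _fit_one_stratum(sub, outcome, covariates, stratum, cluster_by,
                     include_sex, scale, interaction=False):
    spec = ModelSpec(
        outcome=outcome, covariates_on=covariates, stratum=stratum,
        period_interaction=interaction, scale=scale,
    )
    di = make_design(
        sub, covariates=covariates, diagnosis_fe=(stratum == "overall"),
        include_sex=include_sex,
    )
    y = sub[outcome].to_numpy(dtype=float)
    cluster = sub[cluster_by] if cluster_by else None
    t = sub["treatment"].to_numpy(dtype=float)
    z = sub["instrument"].to_numpy(dtype=float)
    if len(sub) < di.X.shape[1] + (2 if interaction else 1) + 2:
        raise _StratumTooSmall(
            stratum, len(sub), di.X.shape[1] + (2 if interaction else 1)
        )
    if np.var(y) == 0:
        raise DegenerateOutcomeError(
            f"outcome {outcome!r} has zero variance in stratum {stratum!r}"
        )
    if not interaction:
        res = TwoStageLS(
            y, t, z, di.X, endog_names=["treatment"],
            instrument_names=["instrument"], exog_names=di.names,
        ).fit(cluster=cluster)
        return _result_from(res, "treatment", spec), res
    late = (sub["period"] == "p2022_23").to_numpy(dtype=float)
    endog = np.column_stack([t, t * late])
    instr = np.column_stack([z, z * late])
    res = TwoStageLS(
        y, endog, instr, di.X,
        endog_names=["treatment", "treatment_x_late"],
        instrument_names=["instrument", "instrument_x_late"],
        exog_names=di.names,
    ).fit(cluster=cluster)
    return _result_from(res, "treatment_x_late", spec), res


class _StratumTooSmall(Exception):
    def __init__(self, stratum, n, k):
        self.stratum, self.n, self.k = stratum, n, k
        super().__init__(f"stratum {stratum!r}: n={n} below {k}+2 parameters")


def run_primary(
    analytic: pd.DataFrame,
    scale: float = 100.0,
    include_sex: bool = False,
    cluster_by: Optional[str] = None,
) -> dict[str, FitResult]:
    """The primary model battery: per-diagnosis 2SLS plus a pooled model.

    Fits one covariate-adjusted 2SLS per diagnosis group and one pooled
    model with diagnosis fixed effects; estimates are reported per ``scale``
    patients.  Strata with too few rows for the design are skipped with a
    logged warning.
    """
    out: dict[str, FitResult] = {}
    for stratum in _strata(analytic):
        sub = analytic if stratum == "overall" else analytic.loc[
            analytic["diagnosis_group"] == stratum
        ]
        try:
            fr, _ = _fit_one_stratum(
                sub, "outcome_count", True, stratum, cluster_by, include_sex, scale
            )
        except (_StratumTooSmall, SingularDesignError) as e:
            logger.warning("skipping stratum %s: %s", stratum, e)
            continue
        out[stratum] = fr
    return out


def run_sensitivities(
    analytic: pd.DataFrame,
    which=("binary", "nocov", "interaction"),
    scale: float = 100.0,
    include_sex: bool = False,
    cluster_by: Optional[str] = None,
) -> dict[str, dict[str, FitResult]]:
    """The sensitivity battery.

    ``binary``: linear-probability 2SLS on the any-follow-up indicator
    (percentage points at the default scale).  ``nocov``: covariate-free
    models (the pooled model keeps only diagnosis fixed effects).
    ``interaction``: treatment and treatment-by-late-period as two endogenous
    terms, instrumented by the preference instrument and its period
    interaction; the reported contrast is the between-period difference in
    the treatment effect.
    """
    out: dict[str, dict[str, FitResult]] = {}
    for name in which:
        results: dict[str, FitResult] = {}
        for stratum in _strata(analytic):
            sub = analytic if stratum == "overall" else analytic.loc[
                analytic["diagnosis_group"] == stratum
            ]
            try:
                if name == "binary":
                    fr, _ = _fit_one_stratum(
                        sub, "any_followup", True, stratum, cluster_by,
                        include_sex, scale,
                    )
                elif name == "nocov":
                    fr, _ = _fit_one_stratum(
                        sub, "outcome_count", False, stratum, cluster_by,
                        include_sex, scale,
                    )
                elif name == "interaction":
                    fr, _ = _fit_one_stratum(
                        sub, "outcome_count", True, stratum, cluster_by,
                        include_sex, scale, interaction=True,
                    )
                else:
                    raise ValueError(f"unknown sensitivity {name!r}")
            except (_StratumTooSmall, SingularDesignError,
                    WeakInstrumentError) as e:
                logger.warning("sensitivity %s: skipping %s: %s", name, stratum, e)
                continue
            results[stratum] = fr
        out[name] = results
    return out
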