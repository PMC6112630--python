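"""Observational regressions and one-sample MR (2SLS) with covariate
adjustment in both stages, multivariable MR, and the negative-control design.

All estimators report heteroskedasticity-robust (HC1 sandwich) standard
errors, normal-approximation 95% CIs (beta +/- 1.96 SE), and a standardised
coefficient ``beta_sd`` = beta / SD(outcome) computed on the analysis sample,
so raw-unit and SD-unit effects can be read side by side.

The negative-control entry point refuses to run unless the outcome's
declared measurement time precedes the exposure's: an instrumented "effect"
on a pre-exposure trait can only reflect instrument invalidity or
confounding, and the time guard is what makes that interpretation safe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grs import DegenerateInstrumentError, instrument_strength

__all__ = [
    "ModelSpec",
    "EstimateRecord",
    "TimeOrderError",
    "WeakInstrumentWarning",
    "fit_observational",
    "fit_2sls",
    "fit_multivariable_mr",
    "run_negative_control",
    "fit_bmi_to_puberty",
]

Z95 = 1.96  # reported-CI convention


class TimeOrderError(ValueError):
    """Adjustment or negative-control variable is not pre-exposure."""


class WeakInstrumentWarning(UserWarning):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what, and how to adjust.

    ``adjustment`` one of none / pre_exposure_confounder /
    pre_exposure_same_trait; when not 'none' every covariate that appears in
    the cohort's declared time ordering must be timestamped before the
    exposure.
    """

    outcome: str
    exposure: str
    covariates: tuple[str, ...] = ()
    adjustment: str = "none"
    instrument: str | None = None

    def __post_init__(self) -> None:
        if self.adjustment not in ("none", "pre_exposure_confounder", "pre_exposure_same_trait"):
            raise ValueError(f"unknown adjustment mode {self.adjustment!r}")


@dataclass
class EstimateRecord:
    """One tidy effect estimate (raw and SD-unit scales)."""

    method: str
    exposure: str
    outcome: str
    adjustment: tuple[str, ...]
    beta: float
    se: float
    p: float
    n: int
    beta_sd: float
    se_sd: float
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ci_low = self.beta - Z95 * self.se
        self.ci_high = self.beta + Z95 * self.se

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "exposure": self.exposure,
            "outcome": self.outcome,
            "adjustment": "+".join(self.adjustment) if self.adjustment else "none",
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "beta_sd": self.beta_sd,
            "se_sd": self.se_sd,
            "n": self.n,
        }


def _check_adjustment_timing(cohort: pd.DataFrame, spec: ModelSpec) -> None:
    if spec.adjustment == "none":
        return
    order = cohort.attrs.get("time_order", {})
    t_exp = order.get(spec.exposure)
    if t_exp is None:
        return
    for cov in spec.covariates:
        t_cov = order.get(cov)
        if t_cov is not None and t_cov >= t_exp:
            raise TimeOrderError(
                f"adjustment variable {cov!r} (t={t_cov}) is not measured "
                f"before the exposure {spec.exposure!r} (t={t_exp})"
            )


def _complete_cases(cohort: pd.DataFrame, cols: list[str], minimum: int) -> pd.DataFrame:
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise KeyError(f"columns not in cohort: {missing}")
    df = cohort[cols].dropna()
    if len(df) < minimum:
        raise ValueError(f"only {len(df)} complete cases; need >= {minimum}")
    return df


def _record(method, spec_exposure, outcome_name, adjustment, beta, se, n, y, diagnostics=None):
    sd_y = float(np.std(y, ddof=1))
    if sd_y == 0:
        raise ValueError(f"outcome {outcome_name!r} has zero variance")
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return EstimateRecord(
        method=method,
        exposure=spec_exposure,
        outcome=outcome_name,
        adjustment=tuple(adjustment),
        beta=float(beta),
        se=float(se),
        p=p,
        n=int(n),
        beta_sd=float(beta / sd_y),
        se_sd=float(se / sd_y),
        diagnostics=diagnostics or {},
    )


def fit_observational(spec: ModelSpec, cohort: pd.DataFrame) -> EstimateRecord:
    """OLS of the outcome on the exposure (+ covariates), HC1 robust SEs."""
    import statsmodels.api as sm

    _check_adjustment_timing(cohort, spec)
    cols = [spec.outcome, spec.exposure, *spec.covariates]
    df = _complete_cases(cohort, cols, minimum=10)
    y = df[spec.outcome].to_numpy(dtype=float)
    if np.std(y, ddof=1) == 0:
        raise ValueError(f"outcome {spec.outcome!r} has zero variance")
    X = sm.add_constant(df[[spec.exposure, *spec.covariates]].astype(float))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design (collinear covariates)")
    res = sm.OLS(y, X).fit(cov_type="HC1")
    return _record(
        "observational", spec.exposure, spec.outcome, spec.covariates,
        res.params[spec.exposure], res.bse[spec.exposure], len(df), y,
    )


def _iv_fit(y: np.ndarray, X: np.ndarray, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2SLS with the correct IV sandwich.

    ``X`` and ``Z`` include the constant and any exogenous covariates
    (covariates instrument themselves). Coefficients solve
    (X'P_Z X) b = X'P_Z y; the covariance uses residuals formed from the
    *observed* regressors, meat Xhat' diag(e^2) Xhat, and an HC1-style
    n/(n-k) correction.
    """
    n, k = X.shape
    Xhat, *_ = np.linalg.lstsq(Z, X, rcond=None)
    Xhat = Z @ Xhat
    A = Xhat.T @ X
    beta = np.linalg.solve(A, Xhat.T @ y)
    e = y - X @ beta
    meat = (Xhat * e[:, None] ** 2).T @ Xhat
    Ainv = np.linalg.inv(A)
    V = Ainv @ meat @ Ainv.T * n / (n - k)
    return beta, V


def _prepare_iv(cohort, spec, score, min_cases):
    score = pd.Series(np.asarray(score, dtype=float), index=cohort.index, name="_score")
    df = pd.concat([cohort, score], axis=1)
    cols = [spec.outcome, spec.exposure, "_score", *spec.covariates]
    df = _complete_cases(df, cols, minimum=min_cases)
    return df


def fit_2sls(
    spec: ModelSpec,
    cohort: pd.DataFrame,
    score,
    weak_f_threshold: float = 10.0,
) -> EstimateRecord:
    """One-sample 2SLS of the outcome on the score-instrumented exposure.

    Covariates enter both stages (they are part of the instrument set and of
    the structural equation). The first-stage F for the score is attached to
    ``diagnostics``; an F below ``weak_f_threshold`` raises a
    ``WeakInstrumentWarning`` but does not fail the fit.
    """
    _check_adjustment_timing(cohort, spec)
    df = _prepare_iv(cohort, spec, score, min_cases=30)
    y = df[spec.outcome].to_numpy(dtype=float)
    n = len(df)
    const = np.ones((n, 1))
    covs = df[list(spec.covariates)].to_numpy(dtype=float) if spec.covariates else np.empty((n, 0))
    X = np.hstack([const, df[[spec.exposure]].to_numpy(dtype=float), covs])
    Z = np.hstack([const, df[["_score"]].to_numpy(dtype=float), covs])
    beta, V = _iv_fit(y, X, Z)

    try:
        if spec.covariates:
            # partial first-stage strength of the score given covariates
            W = np.hstack([const, covs])
            resid = lambda v: v - W @ np.linalg.lstsq(W, v, rcond=None)[0]
            strength = instrument_strength(
                resid(df["_score"].to_numpy()), resid(df[spec.exposure].to_numpy())
            )
        else:
            strength = instrument_strength(df["_score"], df[spec.exposure])
        f_val, r2_val = strength.f, strength.r2
    except DegenerateInstrumentError:
        if np.var(df["_score"].to_numpy()) == 0:
            raise
        # noise-free instrument (exposure == score): 2SLS degenerates to OLS
        f_val, r2_val = float("inf"), 1.0
    if f_val < weak_f_threshold:
        warnings.warn(
            f"weak instrument: first-stage F = {f_val:.2f} < {weak_f_threshold}",
            WeakInstrumentWarning,
            stacklevel=2,
        )
    diag = {"first_stage_f": f_val, "first_stage_r2": r2_val}
    return _record(
        "2sls", spec.exposure, spec.outcome, spec.covariates,
        beta[1], np.sqrt(V[1, 1]), n, y, diagnostics=diag,
    )


def fit_multivariable_mr(
    cohort: pd.DataFrame,
    scores: pd.DataFrame,
    exposures: tuple[str, str],
    outcome: str,
    covariates: tuple[str, ...] = (),
) -> list[EstimateRecord]:
    """Multivariable MR with two scores and two measured exposures.

    Each exposure is regressed on *both* scores (first stage); the outcome is
    then regressed on both predicted exposures jointly, so each coefficient
    is a direct effect holding the other genetically predicted exposure
    fixed. Raises if the predicted exposures are near-collinear.
    """
    if scores.shape[1] != 2 or len(exposures) != 2:
        raise ValueError("need exactly two scores and two exposures")
    df = pd.concat([cohort, scores.add_prefix("_s_")], axis=1)
    score_cols = [f"_s_{c}" for c in scores.columns]
    cols = [outcome, *exposures, *score_cols, *covariates]
    df = _complete_cases(df, cols, minimum=30)
    n = len(df)
    const = np.ones((n, 1))
    covs = df[list(covariates)].to_numpy(dtype=float) if covariates else np.empty((n, 0))
    Z = np.hstack([const, df[score_cols].to_numpy(dtype=float), covs])
    X = np.hstack([const, df[list(exposures)].to_numpy(dtype=float), covs])

    Xhat = Z @ np.linalg.lstsq(Z, X, rcond=None)[0]
    pred = Xhat[:, 1:3]
    cc = np.corrcoef(pred.T)[0, 1]
    if not np.isfinite(cc) or abs(cc) > 0.999:
        raise ValueError(
            f"predicted exposures {exposures[0]!r} and {exposures[1]!r} are collinear (r = {cc:.4f})"
        )
    beta, V = _iv_fit(df[outcome].to_numpy(dtype=float), X, Z)
    y = df[outcome].to_numpy(dtype=float)
    out = []
    for i, exp_name in enumerate(exposures):
        out.append(
            _record(
                "mvmr", exp_name, outcome, covariates,
                beta[1 + i], np.sqrt(V[1 + i, 1 + i]), n, y,
                diagnostics={"joint_exposures": exposures},
            )
        )
    return out


def run_negative_control(
    cohort: pd.DataFrame,
    score,
    exposure: str,
    pre_exposure_outcome: str,
    covariates: tuple[str, ...] = (),
) -> EstimateRecord:
    """2SLS against an outcome declared *before* the exposure.

    Hard-errors unless the cohort's time ordering places the outcome strictly
    before the exposure -- that temporal guard is the design's point. The
    returned record is tagged ``negative_control``; a nonzero estimate
    indicates instrument invalidity or confounding, never a causal effect.
    """
    order = cohort.attrs.get("time_order")
    if not order:
        raise TimeOrderError("cohort declares no time ordering; cannot certify negative control")
    t_out, t_exp = order.get(pre_exposure_outcome), order.get(exposure)
    if t_out is None or t_exp is None:
        raise TimeOrderError(
            f"time ordering missing for {pre_exposure_outcome!r} or {exposure!r}"
        )
    if not t_out < t_exp:
        raise TimeOrderError(
            f"outcome {pre_exposure_outcome!r} (t={t_out}) is not measured before "
            f"exposure {exposure!r} (t={t_exp}); refusing negative-control analysis"
        )
    spec = ModelSpec(outcome=pre_exposure_outcome, exposure=exposure, covariates=covariates)
    rec = fit_2sls(spec, cohort, score)
    rec.method = "negative_control"
    return rec


def fit_bmi_to_puberty(
    cohort: pd.DataFrame,
    bmi_score,
    confounder: str = "confounder",
    puberty_age: str = "exposure",
    covariates: tuple[str, ...] = (),
) -> EstimateRecord:
    """Reverse-direction MR: instrumented childhood adiposity on puberty age."""
    spec = ModelSpec(outcome=puberty_age, exposure=confounder, covariates=covariates)
    rec = fit_2sls(spec, cohort, bmi_score)
    rec.method = "bmi_to_puberty"
    return rec
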