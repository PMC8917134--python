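"""Survival evaluation: Kaplan-Meier, log-rank, Cox tables, IPCW
time-dependent ROC/AUC, risk-score dichotomisation and frozen-signature
validation.

The time-dependent ROC uses the cumulative/dynamic definition at a horizon
t: cases are samples with an observed event by t, controls are samples still
under observation after t.  Case contributions are weighted by the inverse
of the Kaplan-Meier estimate of the censoring survival function evaluated
just before each case's event time (marginal inverse-probability-of-
censoring weighting); with no censoring the AUC reduces exactly to the
Mann-Whitney statistic with ties counted 1/2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from ._cox import efron_newton_binary
from .exceptions import FitError
from .pairs import pair_indicators
from .selection import SignatureModel, compute_risk_score

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers


@dataclass
class KMEstimate:
    """Product-limit survival estimate evaluated at the event times."""

    event_times: np.ndarray
    survival_prob: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function value S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_prob[idx])


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


@dataclass
class CoxResult:
    """Per-covariate Wald summaries of a (multivariate) Cox PH fit."""

    table: pd.DataFrame  # beta, hazard_ratio, ci_low, ci_high, p_value
    log_likelihood: float
    n: int
    n_events: int


@dataclass
class TimeROC:
    horizon_t: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    n_cases: int = 0
    n_controls: int = 0


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


def _surv_arrays(surv: pd.DataFrame):
    return surv["time"].to_numpy(dtype=float), surv["event"].to_numpy(dtype=int)


def km_estimate(surv: pd.DataFrame) -> KMEstimate:
    """Kaplan-Meier product-limit estimator with right censoring; samples
    censored at an event time are counted at risk at that time."""
    if len(surv) == 0:
        raise FitError("empty survival table")
    time, event = _surv_arrays(surv)
    if (time <= 0).all():
        raise FitError("all survival times are non-positive")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    tbl = kmf.event_table
    ev = tbl[tbl["observed"] > 0]
    sf = kmf.survival_function_["KM_estimate"]
    return KMEstimate(
        event_times=ev.index.to_numpy(dtype=float),
        survival_prob=sf.loc[ev.index].to_numpy(dtype=float),
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        n_events=ev["observed"].to_numpy(dtype=int),
    )


def log_rank_test(surv: pd.DataFrame, groups: pd.Series | dict) -> LogRankResult:
    """Log-rank test across two or more groups (df = n_groups - 1)."""
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    g = surv["sample_id"].map(groups)
    if g.isna().any():
        raise FitError("every survival sample needs a group label")
    labels = g.unique()
    if len(labels) < 2:
        raise FitError(f"log-rank test needs >= 2 groups, got {len(labels)}")
    time, event = _surv_arrays(surv)
    res = multivariate_logrank_test(time, g.to_numpy(), event)
    return LogRankResult(
        chi_square=float(res.test_statistic),
        df=len(labels) - 1,
        p_value=float(res.p_value),
    )


# ---------------------------------------------------------------------------
# Cox fits


def cox_fit(covariates: pd.DataFrame, surv: pd.DataFrame) -> CoxResult:
    """Multivariate Cox PH fit (Efron ties) over numeric covariates.

    ``covariates`` must carry a ``sample_id`` column; remaining columns are
    the model terms.  Used both for univariate tables and for the risk-score
    independence test against age/gender/grade/stage.
    """
    if "sample_id" not in covariates.columns:
        raise FitError("covariate table needs a 'sample_id' column")
    merged = covariates.merge(surv[["sample_id", "time", "event"]], on="sample_id", how="inner")
    if len(merged) == 0:
        raise FitError("no overlapping samples between covariates and survival")
    cols = [c for c in covariates.columns if c != "sample_id"]
    X = merged[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise FitError("covariates contain missing values")
    const = [c for c in cols if merged[c].nunique() == 1]
    if const:
        raise FitError(f"constant covariate column(s): {const}")
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < len(cols):
        raise FitError("covariate matrix is rank deficient (collinear columns)")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(merged[cols + ["time", "event"]], duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise FitError(f"Cox model failed to converge: {exc}") from exc
    if (cph.params_.abs() > 10).any():
        warnings.warn("|beta| > 10 suggests separation in the Cox fit", stacklevel=2)
    s = cph.summary
    table = pd.DataFrame(
        {
            "beta": s["coef"],
            "hazard_ratio": s["exp(coef)"],
            "ci_low": s["exp(coef) lower 95%"],
            "ci_high": s["exp(coef) upper 95%"],
            "p_value": s["p"],
        }
    )
    return CoxResult(
        table=table,
        log_likelihood=float(cph.log_likelihood_),
        n=len(merged),
        n_events=int(merged["event"].sum()),
    )


# ---------------------------------------------------------------------------
# IPCW time-dependent ROC


def _align_scores(scores: pd.DataFrame, surv: pd.DataFrame):
    merged = scores.merge(surv[["sample_id", "time", "event"]], on="sample_id", how="inner")
    if len(merged) == 0:
        raise FitError("no overlapping samples between scores and survival")
    return (
        merged["risk_score"].to_numpy(dtype=float),
        merged["time"].to_numpy(dtype=float),
        merged["event"].to_numpy(dtype=int),
        merged,
    )


def _censoring_km_left(time: np.ndarray, event: np.ndarray):
    """Step-function lookup for G(t-): the Kaplan-Meier estimate of the
    censoring survival function evaluated just before t."""
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=1 - event)
    sf = kmf.survival_function_["KM_estimate"]
    knots = sf.index.to_numpy(dtype=float)
    vals = sf.to_numpy(dtype=float)

    def g_left(t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(knots, t, side="left") - 1
        out = np.ones(len(t))
        pos = idx >= 0
        out[pos] = vals[idx[pos]]
        return out

    return g_left


def time_dependent_roc(scores: pd.DataFrame, surv: pd.DataFrame, horizon_t: float) -> TimeROC:
    """Cumulative/dynamic time-dependent ROC with marginal IPCW weights.

    Cases: event time <= t with event observed; controls: observed time > t.
    sensitivity(c) = IPCW-weighted fraction of cases with score > c;
    specificity(c) = fraction of controls with score <= c.  AUC by
    trapezoidal integration, so score ties contribute 1/2.
    """
    s, time, event, _ = _align_scores(scores, surv)
    cases = (time <= horizon_t) & (event == 1)
    controls = time > horizon_t
    if not cases.any() or not controls.any():
        raise FitError(
            f"horizon t={horizon_t}: need at least one case and one control "
            f"(got {int(cases.sum())} cases, {int(controls.sum())} controls)"
        )
    g_left = _censoring_km_left(time, event)
    w = np.zeros(len(s))
    gvals = g_left(time[cases])
    if (gvals <= 0).any():
        raise FitError("censoring survival estimate hits 0 before a case event time")
    w[cases] = 1.0 / gvals

    thresholds = np.concatenate([[-np.inf], np.unique(s)])
    case_scores = s[cases]
    case_w = w[cases]
    ctrl_scores = s[controls]
    wsum = case_w.sum()
    n_ctrl = int(controls.sum())
    sens = np.array([case_w[case_scores > c].sum() / wsum for c in thresholds])
    spec = np.array([(ctrl_scores <= c).sum() / n_ctrl for c in thresholds])
    # integrate in threshold order: fpr runs 1 -> 0, so the signed area is
    # negated; keeping curve order (not re-sorting) preserves the staircase
    # and gives score ties exactly half credit
    fpr = 1.0 - spec
    auc = float(-np.trapezoid(sens, fpr))
    return TimeROC(
        horizon_t=float(horizon_t),
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        n_cases=int(cases.sum()),
        n_controls=n_ctrl,
    )


# ---------------------------------------------------------------------------
# cutoff selection and grouping


def optimal_cutoff(
    scores: pd.DataFrame,
    surv: pd.DataFrame,
    horizon_t: float,
    method: str = "aic",
    min_group_frac: float = 0.1,
) -> float:
    """Optimal risk-score dichotomisation cutoff.

    method="aic": over candidate cutoffs (midpoints of adjacent unique
    scores leaving at least ``min_group_frac`` of samples on each side),
    fit a one-covariate Cox model on the dichotomised indicator and return
    the cutoff minimising AIC.  method="youden": the ROC threshold at
    ``horizon_t`` maximising sensitivity + specificity - 1.  Ties go to the
    smaller cutoff.
    """
    s, time, event, _ = _align_scores(scores, surv)
    uniq = np.unique(s)
    if len(uniq) < 2:
        raise FitError("all risk scores identical; no cutoff exists")
    if method == "aic":
        mids = (uniq[:-1] + uniq[1:]) / 2.0
        n = len(s)
        n_high = np.array([(s > c).sum() for c in mids])
        ok = (n_high >= min_group_frac * n) & ((n - n_high) >= min_group_frac * n)
        if not ok.any():
            raise FitError(
                f"no candidate cutoff leaves >= {min_group_frac:.0%} of samples in each group"
            )
        cands = mids[ok]
        X = (s[:, None] > cands[None, :]).astype(float)
        res = efron_newton_binary(time, event, X)
        return float(cands[int(np.argmin(res.aic))])
    if method == "youden":
        roc = time_dependent_roc(scores, surv, horizon_t)
        finite = np.isfinite(roc.thresholds)
        j = roc.sensitivity[finite] + roc.specificity[finite] - 1.0
        thr = roc.thresholds[finite]
        return float(thr[int(np.argmax(j))])
    raise ValueError(f"unknown cutoff method {method!r}")


def assign_groups(scores: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Label samples high when score > cutoff, else low (boundary -> low)."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    out = scores.copy()
    out["group"] = np.where(out["risk_score"].to_numpy() > cutoff, "high", "low")
    return out


# ---------------------------------------------------------------------------
# frozen-signature validation


@dataclass
class ValidationReport:
    """External-validation summary for a frozen signature."""

    scores: pd.DataFrame
    group_sizes: dict[str, int]
    aucs: dict[float, float]
    log_rank: LogRankResult | None
    km_curves: dict[str, KMEstimate] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "group_sizes": self.group_sizes,
            "aucs": {str(k): v for k, v in self.aucs.items()},
            "log_rank": None
            if self.log_rank is None
            else {
                "chi_square": self.log_rank.chi_square,
                "df": self.log_rank.df,
                "p_value": self.log_rank.p_value,
            },
        }


def validate_frozen_signature(
    model: SignatureModel,
    expr: pd.DataFrame,
    surv: pd.DataFrame,
    horizons: list[float],
) -> ValidationReport:
    """Apply a frozen signature (pairs, betas, cutoff) to an external cohort.

    Recomputes pair indicators, risk scores and high/low groups with no
    refitting, then reports time-dependent AUC at each horizon and the
    between-group log-rank test.
    """
    if model.cutoff is None:
        raise FitError("signature has no frozen cutoff; set one before validation")
    missing = [g for g in model.genes if g not in expr.index]
    if missing:
        raise KeyError(f"signature genes missing from expression matrix: {missing}")
    pm = pair_indicators(expr, model.pairs)
    scored = assign_groups(compute_risk_score(model, pm), model.cutoff)
    merged = scored.merge(surv[["sample_id", "time", "event"]], on="sample_id", how="inner")
    sizes = merged["group"].value_counts().to_dict()
    aucs: dict[float, float] = {}
    for t in horizons:
        try:
            aucs[float(t)] = time_dependent_roc(scored, surv, t).auc
        except FitError as exc:
            logger.warning("AUC at horizon %s unavailable: %s", t, exc)
            aucs[float(t)] = float("nan")
    lr = None
    if merged["group"].nunique() == 2:
        lr = log_rank_test(merged, merged.set_index("sample_id")["group"])
    else:
        warnings.warn("only one risk group in validation cohort; log-rank skipped",
                      stacklevel=2)
    km_curves = {
        g: km_estimate(merged[merged["group"] == g]) for g in sorted(merged["group"].unique())
    }
    return ValidationReport(
        scores=scored, group_sizes=sizes, aucs=aucs, log_rank=lr, km_curves=km_curves
    )
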