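"""Staged reduction of a pair matrix to a prognostic signature.

Stage 1 screens every pair with a univariate Cox proportional-hazards model
and keeps those with Wald p below a threshold.  Stage 2 stabilises an
L1-penalised Cox fit by repeating cross-validated penalty selection many
times under reshuffled folds and keeping pairs with nonzero coefficients in
a stated fraction of repeats.  Stage 3 runs bidirectional stepwise
multivariate Cox selection (AIC-ranked entry gated by a p-value threshold,
p-gated removal) and returns the fitted coefficients.  The risk score of a
sample is the plain linear predictor sum(beta_i * lambda_i) over the
signature pairs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from ._cox import cox_loglik_breslow, efron_newton_binary
from .exceptions import ConfigurationError, FitError
from .pairs import PairMatrix, pair_id

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# shared plumbing


def _align(pm: PairMatrix, surv: pd.DataFrame):
    """Inner-join pair matrix samples with the survival table."""
    surv = surv.drop_duplicates(subset="sample_id")
    common = [s for s in pm.sample_ids if s in set(surv["sample_id"])]
    if not common:
        raise FitError("no overlapping sample IDs between pair matrix and survival table")
    dropped = (len(pm.sample_ids) - len(common)) + (len(surv) - len(common))
    if dropped:
        logger.info("dropped %d samples absent from one of the two tables", dropped)
    s = surv.set_index("sample_id").loc[common]
    ind = pm.indicators[common]
    return ind, s["time"].to_numpy(dtype=float), s["event"].to_numpy(dtype=int), common


# ---------------------------------------------------------------------------
# signature model


@dataclass
class SignatureModel:
    """A frozen pair signature: ordered pairs, Cox coefficients, optional
    risk-score cutoff and the selection settings that produced it."""

    pairs: list[tuple[str, str]]
    betas: list[float]
    cutoff: float | None = None
    endpoint: str = "OS"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.betas):
            raise ValueError("pairs and betas must have equal length")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate pairs in signature")

    @property
    def pair_ids(self) -> list[str]:
        return [pair_id(a, b) for a, b in self.pairs]

    @property
    def genes(self) -> list[str]:
        seen: list[str] = []
        for a, b in self.pairs:
            for g in (a, b):
                if g not in seen:
                    seen.append(g)
        return seen

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "pairs": [
                {"gene_a": a, "gene_b": b, "beta": beta}
                for (a, b), beta in zip(self.pairs, self.betas)
            ],
            "cutoff": self.cutoff,
            "settings": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureModel":
        return cls(
            pairs=[(p["gene_a"], p["gene_b"]) for p in d["pairs"]],
            betas=[float(p["beta"]) for p in d["pairs"]],
            cutoff=None if d.get("cutoff") is None else float(d["cutoff"]),
            endpoint=d.get("endpoint", "OS"),
            provenance=d.get("settings", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "SignatureModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# stage 1: univariate screen


def univariate_cox_screen(
    pm: PairMatrix,
    surv: pd.DataFrame,
    alpha: float = 0.05,
    return_all: bool = False,
) -> pd.DataFrame:
    """Univariate Cox screen of every pair indicator.

    Fits one single-covariate Cox PH model per pair (Efron ties, vectorised
    Newton across pairs) and returns the pairs with Wald p < ``alpha``
    together with hazard ratios and 95% confidence intervals.  Constant
    pairs are skipped with a warning.  With ``return_all`` the full table is
    returned with a ``selected`` column.
    """
    ind, time, event, _ = _align(pm, surv)
    if event.sum() < 2:
        raise FitError(f"need at least 2 events for screening, got {int(event.sum())}")
    X = ind.to_numpy(dtype=float).T  # n x P
    variable = (X.min(axis=0) != X.max(axis=0))
    n_const = int((~variable).sum())
    if n_const:
        warnings.warn(f"skipped {n_const} constant pair(s) during screening", stacklevel=2)
    if not variable.any():
        raise FitError("all pairs are constant; nothing to screen")
    res = efron_newton_binary(time, event, X[:, variable])
    ci_lo, ci_hi = res.confint()
    table = pd.DataFrame(
        {
            "gene_a": [a for (a, _), v in zip(pm.pairs, variable) if v],
            "gene_b": [b for (_, b), v in zip(pm.pairs, variable) if v],
            "beta": res.beta,
            "hazard_ratio": res.hazard_ratio,
            "ci_low": ci_lo,
            "ci_high": ci_hi,
            "p_value": res.p_value,
            "converged": res.converged,
        },
        index=ind.index[variable],
    )
    table["selected"] = table["p_value"] < alpha
    logger.info(
        "univariate screen: %d of %d pairs pass p < %g",
        int(table["selected"].sum()), len(table), alpha,
    )
    return table if return_all else table.loc[table["selected"]].drop(columns="selected")


# ---------------------------------------------------------------------------
# stage 2: repeated cross-validated LASSO


@dataclass
class LassoSelection:
    """Outcome of stability selection: kept pair ids and the per-pair
    fraction of repeats in which each pair had a nonzero coefficient."""

    selected: list[str]
    frequencies: pd.Series
    settings: dict = field(default_factory=dict)


def _fold_deviance(X, time, event, train, test, alphas) -> np.ndarray:
    """Held-out partial-likelihood deviance per penalty for one CV fold."""
    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, alphas=alphas, fit_baseline_model=False, max_iter=100000
    )
    y_train = Surv.from_arrays(event=event[train].astype(bool), time=time[train])
    model.fit(X[train], y_train)
    dev = np.full(len(alphas), np.nan)
    eta = X[test] @ model.coef_  # n_test x n_fitted_alphas
    fitted = np.searchsorted(-np.asarray(alphas), -np.asarray(model.alphas_))
    for col, ai in enumerate(fitted):
        dev[ai] = -2.0 * cox_loglik_breslow(time[test], event[test], eta[:, col])
    return dev


def lasso_select(
    pm: PairMatrix,
    surv: pd.DataFrame,
    n_repeats: int = 1000,
    keep_frac: float = 0.5,
    seed: int = 0,
    n_folds: int = 10,
    n_alphas: int = 50,
    alpha_min_ratio: float = 0.01,
) -> LassoSelection:
    """Stabilised L1-penalised Cox selection.

    Runs ``n_repeats`` rounds of k-fold cross-validated penalty choice
    (folds reshuffled each round from ``seed``); each round selects the
    penalty minimising held-out partial-likelihood deviance and records
    which pairs have nonzero coefficients in the full-data path at that
    penalty.  Pairs selected in at least ``keep_frac`` of the rounds are
    kept.
    """
    if n_repeats < 1:
        raise ConfigurationError("n_repeats must be >= 1")
    ind, time, event, _ = _align(pm, surv)
    if int(event.sum()) < n_folds:
        raise FitError(
            f"{int(event.sum())} events cannot support {n_folds}-fold CV; "
            "use a smaller number of folds"
        )
    X = ind.to_numpy(dtype=float).T
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    path = CoxnetSurvivalAnalysis(
        l1_ratio=1.0,
        n_alphas=n_alphas,
        alpha_min_ratio=alpha_min_ratio,
        fit_baseline_model=False,
        max_iter=100000,
    )
    path.fit(X, y)
    alphas = np.asarray(path.alphas_)
    full_nonzero = path.coef_ != 0.0  # p x n_alphas

    fold_seeds = np.random.SeedSequence(seed).generate_state(n_repeats)
    counts = np.zeros(X.shape[1])
    for r in range(n_repeats):
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=int(fold_seeds[r] % (2**31)))
        dev = np.zeros(len(alphas))
        valid = np.ones(len(alphas), dtype=bool)
        for train, test in kf.split(X):
            if event[train].sum() < 2 or event[test].sum() < 1:
                continue
            d = _fold_deviance(X, time, event, train, test, alphas)
            good = ~np.isnan(d)
            valid &= good
            dev[good] += d[good]
        if not valid.any():
            continue
        dev[~valid] = np.inf
        best = int(np.argmin(dev))
        counts += full_nonzero[:, best]
    freq = pd.Series(counts / n_repeats, index=ind.index, name="selection_frequency")
    selected = [pid for pid in ind.index if freq[pid] >= keep_frac]
    logger.info(
        "stability selection kept %d of %d pairs (keep_frac=%.2f, %d repeats)",
        len(selected), len(freq), keep_frac, n_repeats,
    )
    return LassoSelection(
        selected=selected,
        frequencies=freq,
        settings={
            "n_repeats": n_repeats,
            "keep_frac": keep_frac,
            "seed": seed,
            "n_folds": n_folds,
        },
    )


# ---------------------------------------------------------------------------
# stage 3: stepwise multivariate Cox


def _fit_multivariate(df: pd.DataFrame, cols: Sequence[str]) -> CoxPHFitter:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df[list(cols) + ["time", "event"]], duration_col="time", event_col="event")
    return cph


def stepwise_cox(
    pm: PairMatrix,
    surv: pd.DataFrame,
    p_enter: float = 0.05,
    max_iter: int = 200,
    endpoint: str = "OS",
) -> SignatureModel:
    """Bidirectional stepwise multivariate Cox selection over candidate pairs.

    Forward steps add the candidate minimising model AIC among those whose
    Wald p-value in the enlarged model is below ``p_enter`` (AIC ties broken
    by candidate order); backward steps drop included pairs whose p-value
    rises to ``p_enter`` or above.  Iterates to a fixed point.  Duplicate
    and constant candidate columns are removed up front, so perfectly
    collinear candidates cannot enter together.  If nothing ever qualifies
    an empty model is returned with a warning.
    """
    if pm.n_pairs == 0:
        raise FitError("empty candidate set for stepwise selection")
    ind, time, event, common = _align(pm, surv)
    df = ind.T.astype(float)
    df["time"] = time
    df["event"] = event

    # drop constant columns, then exact duplicates (keep first in order)
    cands: list[str] = []
    seen_rows: dict[bytes, str] = {}
    for pid in ind.index:
        col = ind.loc[pid].to_numpy()
        if col.min() == col.max():
            continue
        key = col.tobytes()
        if key in seen_rows:
            logger.info("candidate %s duplicates %s; dropped", pid, seen_rows[key])
            continue
        seen_rows[key] = pid
        cands.append(pid)
    if not cands:
        warnings.warn("no usable (non-constant) candidates for stepwise selection", stacklevel=2)
        return SignatureModel(pairs=[], betas=[], endpoint=endpoint)

    included: list[str] = []
    seen_states: set[frozenset] = set()
    for _ in range(max_iter):
        changed = False
        # forward step
        best: tuple[float, int, str] | None = None
        for order_idx, c in enumerate(cands):
            if c in included:
                continue
            try:
                fit = _fit_multivariate(df, included + [c])
            except (ConvergenceError, np.linalg.LinAlgError, ValueError):
                continue
            p = float(fit.summary.loc[c, "p"])
            if p < p_enter:
                aic = float(fit.AIC_partial_)
                if best is None or aic < best[0] - 1e-12:
                    best = (aic, order_idx, c)
        if best is not None:
            included.append(best[2])
            changed = True
        # backward step
        while included:
            fit = _fit_multivariate(df, included)
            ps = fit.summary["p"]
            worst = str(ps.idxmax())
            if float(ps[worst]) >= p_enter:
                included.remove(worst)
                changed = True
            else:
                break
        state = frozenset(included)
        if not changed or state in seen_states:
            break
        seen_states.add(state)

    if not included:
        warnings.warn("stepwise selection retained no pair at the inclusion threshold",
                      stacklevel=2)
        return SignatureModel(pairs=[], betas=[], endpoint=endpoint,
                              provenance={"p_enter": p_enter})

    fit = _fit_multivariate(df, included)
    lut = {pair_id(a, b): (a, b) for a, b in pm.pairs}
    return SignatureModel(
        pairs=[lut[c] for c in included],
        betas=[float(fit.params_[c]) for c in included],
        endpoint=endpoint,
        provenance={"p_enter": p_enter, "n_candidates": len(cands), "n_samples": len(common)},
    )


# ---------------------------------------------------------------------------
# risk scores


def compute_risk_score(model: SignatureModel, pm: PairMatrix) -> pd.DataFrame:
    """Risk score per sample: the linear predictor sum(beta_i * lambda_i)
    over the signature pairs; no intercept, no normalisation."""
    betas = np.asarray(model.betas, dtype=float)
    if np.isnan(betas).any():
        raise FitError("signature contains NaN coefficients")
    missing = [p for p in model.pair_ids if p not in pm.indicators.index]
    if missing:
        raise KeyError(f"signature pairs missing from pair matrix: {missing}")
    lam = pm.indicators.loc[model.pair_ids].to_numpy(dtype=float)
    scores = lam.T @ betas if len(betas) else np.zeros(len(pm.sample_ids))
    out = pd.DataFrame({"sample_id": pm.sample_ids, "risk_score": scores})
    return out
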