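"""Synthetic survival cohorts with planted gene-pair effects.

Generates the statistical structure the signature pipeline assumes: a
log-normal expression matrix over a few hundred genes, a small set of causal
pairs whose within-sample indicators enter a Weibull proportional-hazards
model, independent exponential censoring calibrated to a target rate, and a
clinical covariate table.  Every output is a pure function of the
configuration and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import ConfigurationError
from .pairs import pair_indicators

logger = logging.getLogger(__name__)

#: MAF Variant_Classification values that count as non-synonymous
NONSYNONYMOUS_CLASSES = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "Splice_Site",
    "In_Frame_Del",
    "In_Frame_Ins",
    "Translation_Start_Site",
    "Nonstop_Mutation",
)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a simulated cohort.

    Defaults mirror a liver-cancer discovery cohort: 374 tumour samples over
    429 candidate genes with roughly two-thirds of patients censored for
    overall survival.  ``causal_betas`` are log-hazard coefficients attached
    to the planted pair indicators.  ``covariate_effects`` optionally adds
    clinical log-hazards (keys among age/gender/grade/stage); by default the
    clinical table is pure noise so signature recovery is unconfounded.
    """

    n_samples: int = 374
    n_genes: int = 429
    n_causal_pairs: int = 3
    causal_betas: Sequence[float] = (1.5, 1.0, -1.0)
    baseline_shape: float = 1.2
    baseline_scale: float = 1825.0
    censor_rate: float = 0.65
    gene_corr: float = 0.2
    seed: int = 0
    covariate_effects: Mapping[str, float] | None = None
    gene_mean_spread: float = 1.0
    gene_sigma: float = 1.0
    causal_freq_band: tuple[float, float] = (0.3, 0.7)

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1 or self.n_causal_pairs < 0:
            raise ConfigurationError("counts must be positive")
        if self.n_causal_pairs > self.n_genes * (self.n_genes - 1) // 2:
            raise ConfigurationError(
                f"{self.n_causal_pairs} causal pairs exceed C({self.n_genes},2)"
            )
        if len(self.causal_betas) != self.n_causal_pairs:
            raise ConfigurationError(
                f"causal_betas has length {len(self.causal_betas)}, "
                f"expected n_causal_pairs={self.n_causal_pairs}"
            )
        if not (0.0 <= self.censor_rate < 1.0):
            raise ConfigurationError("censor_rate must lie in [0, 1)")
        if not (0.0 <= self.gene_corr < 1.0):
            raise ConfigurationError("gene_corr must lie in [0, 1)")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ConfigurationError("Weibull shape and scale must be > 0")
        bad = set(self.covariate_effects or {}) - {"age", "gender", "grade", "stage"}
        if bad:
            raise ConfigurationError(f"unknown covariate effects: {sorted(bad)}")


@dataclass
class SimCohort:
    """A simulated cohort: expression, survival and clinical tables plus the
    planted truth as (gene_a, gene_b, beta) triples."""

    expression: pd.DataFrame
    survival: pd.DataFrame
    clinical: pd.DataFrame
    truth: list[tuple[str, str, float]]
    config: SimConfig | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.columns)

    def true_linear_predictor(self) -> pd.Series:
        """Sum of beta * indicator over the planted pairs, per sample."""
        eta = pd.Series(0.0, index=self.expression.columns, name="eta")
        if self.truth:
            pm = pair_indicators(self.expression, [(a, b) for a, b, _ in self.truth])
            betas = np.array([b for _, _, b in self.truth])
            eta += pm.indicators.to_numpy(dtype=float).T @ betas
        return eta

    def subset(self, sample_ids: Sequence[str]) -> "SimCohort":
        sample_ids = list(sample_ids)
        return SimCohort(
            expression=self.expression[sample_ids],
            survival=self.survival.set_index("sample_id").loc[sample_ids].reset_index(),
            clinical=self.clinical.set_index("sample_id").loc[sample_ids].reset_index(),
            truth=list(self.truth),
            config=self.config,
        )

    def split(self, n_first: int) -> tuple["SimCohort", "SimCohort"]:
        """Split into two cohorts sharing the same generative truth."""
        ids = self.sample_ids
        return self.subset(ids[:n_first]), self.subset(ids[n_first:])


def _draw_expression(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    genes = [f"LINC{i + 1:04d}" for i in range(cfg.n_genes)]
    samples = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]
    mu = rng.normal(0.0, cfg.gene_mean_spread, size=cfg.n_genes)
    rho = cfg.gene_corr
    shared = rng.normal(size=cfg.n_samples)
    noise = rng.normal(size=(cfg.n_genes, cfg.n_samples))
    z = np.sqrt(rho) * shared[None, :] + np.sqrt(1.0 - rho) * noise
    vals = np.exp(mu[:, None] + cfg.gene_sigma * z)
    return pd.DataFrame(vals, index=genes, columns=samples)


def _choose_causal_pairs(
    cfg: SimConfig, expr: pd.DataFrame, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Disjoint gene pairs whose indicator frequency falls in the target band,
    so planted pairs are informative and survive the constancy filter."""
    lo, hi = cfg.causal_freq_band
    genes = list(expr.index)
    vals = expr.to_numpy(dtype=float)
    chosen: list[tuple[str, str]] = []
    used: set[int] = set()
    for _ in range(10000):
        if len(chosen) == cfg.n_causal_pairs:
            break
        i, j = rng.choice(cfg.n_genes, size=2, replace=False)
        if i in used or j in used:
            continue
        f = float(np.mean(vals[i] > vals[j]))
        if lo <= f <= hi:
            chosen.append((genes[i], genes[j]))
            used.update((int(i), int(j)))
    if len(chosen) < cfg.n_causal_pairs:
        raise ConfigurationError(
            "could not find enough disjoint causal pairs in the requested "
            f"frequency band {cfg.causal_freq_band}; widen the band or add genes"
        )
    return chosen


def _covariate_eta(cfg: SimConfig, clinical: pd.DataFrame) -> np.ndarray:
    """Clinical contribution to the log-hazard, on standardized scales:
    age per decade from 60, gender as 0/1, grade/stage centred at 2.5."""
    eff = cfg.covariate_effects or {}
    eta = np.zeros(len(clinical))
    if "age" in eff:
        eta += eff["age"] * (clinical["age"].to_numpy() - 60.0) / 10.0
    if "gender" in eff:
        eta += eff["gender"] * clinical["gender"].to_numpy()
    if "grade" in eff:
        eta += eff["grade"] * (clinical["grade"].to_numpy() - 2.5)
    if "stage" in eff:
        eta += eff["stage"] * (clinical["stage"].to_numpy() - 2.5)
    return eta


def _censoring_rate_for(times: np.ndarray, target: float) -> float:
    """Exponential censoring rate r with mean P(C < T) equal to target,
    solved on the realized event times."""
    def gap(r: float) -> float:
        return float(np.mean(1.0 - np.exp(-r * times))) - target

    hi = 1.0 / max(times.min(), 1e-12) * 50.0
    lo = 1e-15
    while gap(hi) < 0:
        hi *= 10.0
    return brentq(gap, lo, hi, xtol=1e-15)


def simulate_cohort(config: SimConfig) -> SimCohort:
    """Draw a full cohort under the configured Weibull proportional-hazards
    model with pair-indicator effects.

    Event times use inverse-transform sampling from
    S(t|x) = exp(-(t/scale)^shape * exp(eta)); censoring is exponential with
    rate calibrated so the expected censored fraction matches
    ``censor_rate``.  Observed time is the minimum, event the indicator of
    the true time coming first.  All times are strictly positive, so the
    zero-follow-up exclusion holds by construction.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    expr = _draw_expression(cfg, rng)
    samples = list(expr.columns)

    causal = _choose_causal_pairs(cfg, expr, rng) if cfg.n_causal_pairs else []
    truth = [(a, b, float(beta)) for (a, b), beta in zip(causal, cfg.causal_betas)]

    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "age": np.round(rng.normal(60.0, 10.0, size=cfg.n_samples), 1),
            "gender": rng.integers(0, 2, size=cfg.n_samples),
            "grade": rng.integers(1, 5, size=cfg.n_samples),
            "stage": rng.integers(1, 5, size=cfg.n_samples),
        }
    )

    eta = np.zeros(cfg.n_samples)
    if truth:
        pm = pair_indicators(expr, [(a, b) for a, b, _ in truth])
        betas = np.array([beta for _, _, beta in truth])
        eta += pm.indicators.to_numpy(dtype=float).T @ betas
    eta += _covariate_eta(cfg, clinical)

    u = rng.uniform(size=cfg.n_samples)
    t_event = cfg.baseline_scale * (-np.log(u) / np.exp(eta)) ** (1.0 / cfg.baseline_shape)

    if cfg.censor_rate == 0.0:
        observed, event = t_event, np.ones(cfg.n_samples, dtype=int)
    else:
        rate = _censoring_rate_for(t_event, cfg.censor_rate)
        c = rng.exponential(1.0 / rate, size=cfg.n_samples)
        observed = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)

    survival = pd.DataFrame(
        {"sample_id": samples, "time": observed, "event": event, "endpoint": "OS"}
    )
    logger.info(
        "simulated cohort: %d samples, %d genes, %d planted pairs, %.1f%% censored",
        cfg.n_samples, cfg.n_genes, len(truth), 100.0 * (1 - event.mean()),
    )
    return SimCohort(expression=expr, survival=survival, clinical=clinical,
                     truth=truth, config=cfg)


def identity_distortion(sample_ids: Sequence[str]) -> pd.DataFrame:
    """Distortion parameter table leaving expression unchanged."""
    return pd.DataFrame(
        {"scale": 1.0, "power": 1.0, "shift": 0.0}, index=list(sample_ids)
    )


def apply_batch_distortion(
    expr: pd.DataFrame,
    seed: int | None = None,
    params: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-sample strictly increasing distortion of a non-negative matrix.

    Each sample column x is mapped to scale * x**power + shift with
    scale, power > 0 and shift >= 0, emulating platform- or batch-level
    monotone re-calibration.  The within-sample gene ranking (including
    ties) is preserved exactly.  Parameters are drawn from ``seed`` unless
    an explicit table (index = sample id; columns scale/power/shift) is
    given.
    """
    if (expr.to_numpy() < 0).any():
        raise ValueError("batch distortion requires non-negative expression")
    if params is None:
        if seed is None:
            raise ValueError("provide either a seed or an explicit parameter table")
        rng = np.random.default_rng(seed)
        n = expr.shape[1]
        params = pd.DataFrame(
            {
                "scale": np.exp(rng.uniform(-1.0, 1.0, size=n)),
                "power": np.exp(rng.uniform(-0.5, 0.5, size=n)),
                "shift": rng.uniform(0.0, 1.0, size=n),
            },
            index=expr.columns,
        )
    params = params.loc[expr.columns]
    if (params["scale"] <= 0).any() or (params["power"] <= 0).any() or (params["shift"] < 0).any():
        raise ValueError("distortion requires scale > 0, power > 0, shift >= 0")
    vals = expr.to_numpy(dtype=float)
    out = params["scale"].to_numpy() * vals ** params["power"].to_numpy() + params["shift"].to_numpy()
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def write_maf_fixture(
    path,
    nonsyn_counts: Mapping[str, int],
    seed: int = 0,
    silent_max: int = 3,
) -> pd.DataFrame:
    """Write a minimal MAF with the requested non-synonymous row count per
    sample plus random decoy ``Silent`` rows, and return it as a DataFrame."""
    rng = np.random.default_rng(seed)
    gene_pool = [f"GENE{i + 1:03d}" for i in range(50)]
    rows = []
    for sample, count in nonsyn_counts.items():
        if count < 0:
            raise ValueError(f"negative mutation count for {sample}")
        for _ in range(int(count)):
            rows.append(
                (
                    gene_pool[rng.integers(len(gene_pool))],
                    NONSYNONYMOUS_CLASSES[rng.integers(len(NONSYNONYMOUS_CLASSES))],
                    sample,
                )
            )
        for _ in range(int(rng.integers(0, silent_max + 1))):
            rows.append((gene_pool[rng.integers(len(gene_pool))], "Silent", sample))
    maf = pd.DataFrame(
        rows, columns=["Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode"]
    )
    with open(path, "w") as fh:
        fh.write("#version 2.4\n")
        maf.to_csv(fh, sep="\t", index=False)
    return maf


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of a configuration with a different seed."""
    return replace(config, seed=seed)
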