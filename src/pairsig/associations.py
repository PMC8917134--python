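"""Risk-group association toolkit.

Correlation, two-/k-group rank comparisons, categorical composition tests,
tumor mutational burden from a MAF, and TMB-by-risk stratified survival.
Immune scores, deconvolution fractions and similar quantities are consumed
as externally supplied per-sample feature columns; this module never
computes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .evaluation import KMEstimate, LogRankResult, km_estimate, log_rank_test
from .exceptions import FitError, FormatError
from .simulate import NONSYNONYMOUS_CLASSES

MAF_REQUIRED_COLUMNS = ("Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode")


def spearman_assoc(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; p from the
    t-approximation.  Missing values are removed pairwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise FitError(f"need >= 4 paired observations, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise FitError("constant input; Spearman correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def group_compare(feature, groups, test: str = "wilcoxon") -> tuple[float, float]:
    """Rank-based comparison of a numeric feature across groups.

    test="wilcoxon": two-group Wilcoxon rank-sum (Mann-Whitney U, normal
    approximation with tie correction).  test="kruskal": Kruskal-Wallis for
    two or more groups.
    """
    feature = np.asarray(feature, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    samples = [feature[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise FitError("empty group in comparison")
    if test == "wilcoxon":
        if len(labels) != 2:
            raise FitError(f"wilcoxon requires exactly 2 groups, got {len(labels)}")
        res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided",
                                 method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    if test == "kruskal":
        if len(labels) < 2:
            raise FitError("kruskal requires >= 2 groups")
        res = stats.kruskal(*samples)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def composition_test(category, groups) -> tuple[float, int, float, pd.DataFrame]:
    """Pearson chi-square (no continuity correction) on the category-by-group
    contingency table.  Returns (chi_square, df, p, expected counts)."""
    tab = pd.crosstab(pd.Series(category, name="category"), pd.Series(groups, name="group"))
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise FitError("contingency table needs >= 2 rows and >= 2 columns")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise FitError("contingency table has an empty row or column")
    chi2, p, dof, expected = stats.chi2_contingency(tab.to_numpy(), correction=False)
    exp = pd.DataFrame(expected, index=tab.index, columns=tab.columns)
    return float(chi2), int(dof), float(p), exp


def tmb_from_maf(maf_path, megabases: float = 38.0, samples=None) -> pd.DataFrame:
    """Tumor mutational burden per sample from a MAF file.

    Counts rows whose Variant_Classification is non-synonymous and divides
    by the sequenced territory in megabases (default 38 Mb, a whole-exome
    convention).  Samples listed in ``samples`` but absent from the MAF get
    TMB 0.
    """
    maf = pd.read_csv(maf_path, sep="\t", comment="#", low_memory=False)
    missing = [c for c in MAF_REQUIRED_COLUMNS if c not in maf.columns]
    if missing:
        raise FormatError(f"MAF {maf_path} missing required columns: {missing}")
    if megabases <= 0:
        raise ValueError("megabases must be positive")
    nonsyn = maf[maf["Variant_Classification"].isin(NONSYNONYMOUS_CLASSES)]
    counts = nonsyn.groupby("Tumor_Sample_Barcode").size()
    if samples is not None:
        counts = counts.reindex(list(samples), fill_value=0)
    out = pd.DataFrame({"sample_id": counts.index, "tmb": counts.to_numpy() / megabases})
    return out.reset_index(drop=True)


def median_split(values: pd.Series, labels=("low", "high")) -> pd.Series:
    """Binary split at the median; values <= median (ties included) are low."""
    med = float(np.median(values))
    return pd.Series(np.where(values > med, labels[1], labels[0]), index=values.index)


@dataclass
class StratifiedSurvival:
    """Four-group survival analysis for two binary factors."""

    km: dict[tuple[str, str], KMEstimate]
    overall: LogRankResult
    within_a: dict[str, LogRankResult]


def stratified_survival(
    surv: pd.DataFrame, factor_a: pd.Series, factor_b: pd.Series
) -> StratifiedSurvival:
    """KM and log-rank over the four cells of two binary factors, plus
    two-group log-rank on ``factor_b`` within each level of ``factor_a``
    (e.g. risk-group effect within TMB-high and TMB-low strata)."""
    df = surv.copy()
    df["a"] = df["sample_id"].map(factor_a)
    df["b"] = df["sample_id"].map(factor_b)
    if df[["a", "b"]].isna().any().any():
        raise FitError("every sample needs labels for both factors")
    a_levels = sorted(df["a"].unique())
    b_levels = sorted(df["b"].unique())
    if len(a_levels) != 2 or len(b_levels) != 2:
        raise FitError("both factors must be binary")
    empty = [
        (a, b)
        for a in a_levels
        for b in b_levels
        if ((df["a"] == a) & (df["b"] == b)).sum() == 0
    ]
    if empty:
        raise FitError(f"empty factor combination cell(s): {empty}")
    km = {
        (a, b): km_estimate(df[(df["a"] == a) & (df["b"] == b)])
        for a in a_levels
        for b in b_levels
    }
    combo = df["a"].astype(str) + "/" + df["b"].astype(str)
    overall = log_rank_test(df, pd.Series(combo.to_numpy(), index=df["sample_id"]))
    within = {}
    for a in a_levels:
        sub = df[df["a"] == a]
        within[a] = log_rank_test(sub, pd.Series(sub["b"].to_numpy(), index=sub["sample_id"]))
    return StratifiedSurvival(km=km, overall=overall, within_a=within)


def association_batch(
    scores: pd.DataFrame, features: pd.DataFrame, tests=("spearman",)
) -> pd.DataFrame:
    """Run the named tests of every numeric feature column against the risk
    score (spearman) or risk group (wilcoxon/kruskal); emits raw p-values
    together with Benjamini-Hochberg adjusted ones."""
    merged = scores.merge(features, on="sample_id", how="inner")
    rows = []
    feat_cols = [c for c in features.columns if c != "sample_id"]
    for test in tests:
        for col in feat_cols:
            if not pd.api.types.is_numeric_dtype(merged[col]):
                continue
            try:
                if test == "spearman":
                    stat, p = spearman_assoc(merged["risk_score"], merged[col])
                elif test in ("wilcoxon", "kruskal"):
                    if "group" not in merged.columns:
                        raise FitError("scores need a 'group' column for group tests")
                    stat, p = group_compare(merged[col], merged["group"], test=test)
                else:
                    raise ValueError(f"unknown test {test!r}")
            except FitError:
                continue
            rows.append({"feature": col, "test": test, "statistic": stat, "p": p})
    out = pd.DataFrame(rows, columns=["feature", "test", "statistic", "p"])
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["p_adj"] = []
    return out
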