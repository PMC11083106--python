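"""Group-level statistics: normality screening, pairwise rank-sum tests,
descriptive summaries, and ROC analysis.

The cohort table is a pandas DataFrame with one row per included case,
a ``group`` column and one column per ADC feature (printed scale,
1e-3 mm^2/s). Small groups (n below ``min_group_n``) are reported
descriptively only, with no significance claims; no multiple-testing
correction is applied by default, with Holm/Bonferroni available behind
a flag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve
from statsmodels.stats.diagnostic import lilliefors

from skindwi.io import DataError

__all__ = [
    "DEFAULT_FEATURES",
    "ComparisonResult",
    "ROCResult",
    "ks_normality",
    "ranksum",
    "pairwise_group_tests",
    "roc_analysis",
    "summarize_groups",
]

DEFAULT_FEATURES = (
    "adc_mean",
    "adc_median",
    "adc_min",
    "adc_max",
    "adc_of_mean_signal",
)

_EXACT_MAX_N = 10


def ks_normality(sample) -> float:
    """One-sample Kolmogorov-Smirnov p-value against a fitted normal.

    The normal's mean/SD are estimated from the sample, which
    invalidates the standard KS null distribution (its p-values become
    grossly conservative); the Lilliefors-corrected p-value is returned
    instead, and is itself approximate (table/Monte-Carlo based).
    Requires n >= 4 and a non-degenerate sample.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise DataError(f"need n >= 4 for the KS normality screen, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DataError("degenerate (constant) sample")
    _, pvalue = lilliefors(x, dist="norm", pvalmethod="table")
    return float(pvalue)


def ranksum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when both samples have n <= 10 and
    there are no ties, and the tie-corrected normal approximation (with
    continuity correction) otherwise. Returns (U statistic of ``x``,
    two-sided p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = x.size <= _EXACT_MAX_N and y.size <= _EXACT_MAX_N and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
    )
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ComparisonResult:
    """One pairwise feature comparison."""

    feature: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float | None
    p_value: float | None
    significant: bool
    descriptive_only: bool


def pairwise_group_tests(
    cohort: pd.DataFrame,
    features=DEFAULT_FEATURES,
    group_col: str = "group",
    alpha: float = 0.05,
    min_group_n: int = 5,
    correction: str | None = None,
) -> pd.DataFrame:
    """Rank-sum tests for every unordered group pair and feature.

    Pairs involving a group with n < ``min_group_n`` are marked
    ``descriptive_only`` and carry no test. ``correction`` may be
    ``None`` (default, matching the original analysis), ``"holm"`` or
    ``"bonferroni"``; correction is applied across the tested
    (non-descriptive) hypotheses.
    """
    groups = sorted(cohort[group_col].dropna().unique())
    results: list[ComparisonResult] = []
    for feature in features:
        if feature not in cohort.columns:
            raise DataError(f"feature {feature!r} not in cohort table")
        for ga, gb in itertools.combinations(groups, 2):
            xa = cohort.loc[cohort[group_col] == ga, feature].dropna().values
            xb = cohort.loc[cohort[group_col] == gb, feature].dropna().values
            descriptive = len(xa) < min_group_n or len(xb) < min_group_n
            if descriptive:
                results.append(
                    ComparisonResult(
                        feature, ga, gb, len(xa), len(xb),
                        None, None, False, True,
                    )
                )
            else:
                stat, p = ranksum(xa, xb)
                results.append(
                    ComparisonResult(
                        feature, ga, gb, len(xa), len(xb),
                        stat, p, p < alpha, False,
                    )
                )

    df = pd.DataFrame([r.__dict__ for r in results])
    if correction is not None and not df.empty:
        tested = df["p_value"].notna()
        pvals = df.loc[tested, "p_value"].values
        m = len(pvals)
        if correction == "bonferroni":
            adj = np.minimum(pvals * m, 1.0)
        elif correction == "holm":
            order = np.argsort(pvals)
            adj = np.empty(m)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, min((m - rank) * pvals[idx], 1.0))
                adj[idx] = running
        else:
            raise DataError(f"unknown correction {correction!r}")
        df.loc[tested, "p_value"] = adj
        df.loc[tested, "significant"] = adj < alpha
    return df


@dataclass
class ROCResult:
    """Empirical ROC curve for one feature and group pair."""

    feature: str
    positive_group: str
    negative_group: str
    lower_is_positive: bool
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    youden_threshold: float
    sensitivity_at_youden: float
    specificity_at_youden: float


def roc_analysis(
    cohort: pd.DataFrame,
    feature: str,
    positive_group: str,
    negative_group: str,
    group_col: str = "group",
    lower_is_positive: bool = True,
) -> ROCResult:
    """Empirical ROC over all distinct thresholds, trapezoid AUC.

    With midrank handling of ties the AUC equals the Mann-Whitney
    U statistic divided by n_pos * n_neg. ``lower_is_positive`` follows
    the diffusion convention that lower ADC indicates the more malignant
    (positive) class. The operating point maximizes the Youden index
    J = sensitivity + specificity - 1.
    """
    pos = cohort.loc[cohort[group_col] == positive_group, feature].dropna()
    neg = cohort.loc[cohort[group_col] == negative_group, feature].dropna()
    if pos.empty or neg.empty:
        raise DataError(
            f"both groups must be nonempty "
            f"(n_pos={len(pos)}, n_neg={len(neg)})"
        )
    values = np.concatenate([pos.values, neg.values])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    scores = -values if lower_is_positive else values
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    k = int(np.argmax(j))
    # map the score threshold back to the feature scale
    thresholds = -thr if lower_is_positive else thr
    return ROCResult(
        feature=feature,
        positive_group=positive_group,
        negative_group=negative_group,
        lower_is_positive=lower_is_positive,
        thresholds=thresholds,
        sensitivities=tpr,
        specificities=1.0 - fpr,
        auc=auc,
        youden_threshold=float(thresholds[k]),
        sensitivity_at_youden=float(tpr[k]),
        specificity_at_youden=float(1.0 - fpr[k]),
    )


def summarize_groups(
    cohort: pd.DataFrame,
    features=DEFAULT_FEATURES,
    group_col: str = "group",
) -> pd.DataFrame:
    """Per group x feature: n, mean, SD, SEM and min-max range.

    All three dispersion measures are printed to sidestep the ambiguity
    of "±" in summary tables; SEM for a single-case group is NaN.
    """
    if cohort.empty:
        raise DataError("cohort table is empty")
    rows = []
    for group, sub in cohort.groupby(group_col, sort=True):
        for feature in features:
            if feature not in cohort.columns:
                raise DataError(f"feature {feature!r} not in cohort table")
            vals = sub[feature].dropna().values
            n = len(vals)
            sd = float(np.std(vals, ddof=1)) if n > 1 else np.nan
            rows.append(
                {
                    "group": group,
                    "feature": feature,
                    "n": n,
                    "mean": float(np.mean(vals)) if n else np.nan,
                    "sd": sd,
                    "sem": sd / np.sqrt(n) if n > 1 else np.nan,
                    "min": float(np.min(vals)) if n else np.nan,
                    "max": float(np.max(vals)) if n else np.nan,
                }
            )
    return pd.DataFrame(rows)
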