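"""Cohort-level correlation, discrimination, and group-comparison statistics.

Correlation between profile readouts is cross-checked three ways: OLS slope
with its two-sided t-test, Spearman's rank rho, and Kendall's tau-b. Cohort
discrimination uses the best separating threshold in the Youden sense
(maximising sensitivity + specificity - 100 over candidate midpoints);
classification consistency is the percentage of subjects classified
identically by two markers. One/two-way ANOVA with Tukey HSD is exposed at
contract level for multi-group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "CorrelationResult",
    "SeparationResult",
    "correlate",
    "best_threshold",
    "classification_consistency",
    "group_compare",
]


@dataclass(frozen=True)
class CorrelationResult:
    slope: float
    intercept: float
    slope_p: float
    pearson_r: float
    spearman_rho: float
    spearman_p: float
    kendall_tau: float
    kendall_p: float
    n: int


@dataclass(frozen=True)
class SeparationResult:
    threshold: float
    sensitivity: float  # %
    specificity: float  # %
    direction: Literal["greater-is-positive", "less-is-positive"]

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 100.0


def correlate(x, y) -> CorrelationResult:
    """OLS slope test plus Spearman and Kendall (tau-b) rank correlations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    lin = _st.linregress(x, y)
    sp = _st.spearmanr(x, y)
    kt = _st.kendalltau(x, y)  # tau-b, handles ties
    return CorrelationResult(
        slope=float(lin.slope),
        intercept=float(lin.intercept),
        slope_p=float(lin.pvalue),
        pearson_r=float(lin.rvalue),
        spearman_rho=float(sp.statistic),
        spearman_p=float(sp.pvalue),
        kendall_tau=float(kt.statistic),
        kendall_p=float(kt.pvalue),
        n=int(x.size),
    )


def _sens_spec(negatives, positives, threshold, direction) -> tuple[float, float]:
    neg = np.asarray(negatives, dtype=float)
    pos = np.asarray(positives, dtype=float)
    if direction == "greater-is-positive":
        sens = np.mean(pos > threshold)
        spec = np.mean(neg <= threshold)
    else:
        sens = np.mean(pos < threshold)
        spec = np.mean(neg >= threshold)
    return 100.0 * float(sens), 100.0 * float(spec)


def best_threshold(negatives, positives) -> SeparationResult:
    """Threshold maximising Youden's J = sensitivity + specificity - 100.

    Candidates are midpoints between consecutive sorted unique pooled values
    (plus outer sentinels); both classification directions are tried and the
    better kept. Ties in J break toward higher specificity.
    """
    neg = np.asarray(negatives, dtype=float)
    pos = np.asarray(positives, dtype=float)
    if neg.size == 0 or pos.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.unique(np.concatenate([neg, pos]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0 if pooled.size > 1 else pooled
    span = max(np.ptp(pooled), 1.0)
    candidates = np.concatenate([[pooled[0] - span], mids, [pooled[-1] + span]])
    best: SeparationResult | None = None
    for direction in ("greater-is-positive", "less-is-positive"):
        for thr in candidates:
            sens, spec = _sens_spec(neg, pos, thr, direction)
            cand = SeparationResult(float(thr), sens, spec, direction)
            if (
                best is None
                or cand.youden_j > best.youden_j + 1e-12
                or (abs(cand.youden_j - best.youden_j) <= 1e-12
                    and cand.specificity > best.specificity)
            ):
                best = cand
    return best


def classification_consistency(labels_a, labels_b) -> float:
    """Percent of subjects with identical binary classification by two markers."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size != b.size or a.size == 0:
        raise ValueError("label vectors must be non-empty and equal length")
    return 100.0 * float(np.mean(a == b))


@dataclass(frozen=True)
class GroupComparison:
    anova: pd.DataFrame  # effect -> F, p
    tukey: pd.DataFrame | None  # pairwise comparisons (one-way, when significant)

    @property
    def p_value(self) -> float:
        """p of the (first) main effect."""
        return float(self.anova["p"].iloc[0])

    @property
    def interaction_p(self) -> float | None:
        if "interaction" in self.anova.index:
            return float(self.anova.loc["interaction", "p"])
        return None


def group_compare(values, factor_a, factor_b=None, alpha: float = 0.05) -> GroupComparison:
    """One- or two-way fixed-effects ANOVA with Tukey HSD follow-up.

    One factor: one-way ANOVA across its levels, Tukey HSD when the F-test is
    significant. Two factors: two-way OLS ANOVA including the interaction
    term (the cross-factor "cooperation" probe).
    """
    values = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    if values.size != fa.size:
        raise ValueError("values and factor_a must have equal length")
    if factor_b is None:
        levels = pd.unique(fa)
        groups = [values[fa == g] for g in levels]
        if any(len(g) == 0 for g in groups) or len(groups) < 2:
            raise ValueError("need >= 2 non-empty groups")
        f, p = _st.f_oneway(*groups)
        anova = pd.DataFrame({"F": [float(f)], "p": [float(p)]}, index=["factor_a"])
        tukey = None
        if p < alpha and len(groups) >= 2:
            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            res = pairwise_tukeyhsd(values, fa, alpha=alpha)
            tukey = pd.DataFrame(
                res.summary().data[1:], columns=res.summary().data[0]
            )
        return GroupComparison(anova=anova, tukey=tukey)
    fb = np.asarray(factor_b)
    if values.size != fb.size:
        raise ValueError("values and factor_b must have equal length")
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": values, "a": fa.astype(str), "b": fb.astype(str)})
    cells = df.groupby(["a", "b"]).size()
    expected = len(df["a"].unique()) * len(df["b"].unique())
    if cells.size < expected:
        raise ValueError("empty cells in the two-factor design")
    model = smf.ols("y ~ C(a) * C(b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    anova = pd.DataFrame(
        {
            "F": [
                float(table.loc["C(a)", "F"]),
                float(table.loc["C(b)", "F"]),
                float(table.loc["C(a):C(b)", "F"]),
            ],
            "p": [
                float(table.loc["C(a)", "PR(>F)"]),
                float(table.loc["C(b)", "PR(>F)"]),
                float(table.loc["C(a):C(b)", "PR(>F)"]),
            ],
        },
        index=["factor_a", "factor_b", "interaction"],
    )
    return GroupComparison(anova=anova, tukey=None)
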