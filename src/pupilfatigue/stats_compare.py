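"""Between-condition comparison of fatigue features.

Each fatigue feature is compared between a reference viewing condition and
one or more modified conditions (e.g. gamma, color-temperature or brightness
manipulations of the stimulus). The default test is Welch's two-sample
t-test — per-subject feature values across independent viewing sessions,
robust to unequal variances — with Student's t, Mann-Whitney U, paired t and
Wilcoxon signed-rank available for paired or non-normal designs. Two-sided
p-values are labelled with significance stars at the p < 0.01 / 0.05 / 0.1
cutoffs. No multiple-testing correction is applied by default (per-comparison
reporting); Holm correction is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

TESTS = ("welch_t", "student_t", "mann_whitney", "paired_t", "wilcoxon")
_PAIRED = ("paired_t", "wilcoxon")


@dataclass(frozen=True)
class ConditionSample:
    """One feature's per-subject (or per-segment) values under one condition."""

    condition: str
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("each condition needs >= 2 values for testing")


@dataclass(frozen=True)
class ComparisonResult:
    feature_name: str
    condition: str
    mean: float
    reference_mean: float
    p_value: float
    stars: str


def star_label(p: float) -> str:
    """Significance stars: *** p<0.01, ** p<0.05, * p<0.1, '' otherwise."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value outside [0, 1]: {p}")
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def _p_value(ref: np.ndarray, cond: np.ndarray, test: str) -> float:
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}; choose from {TESTS}")
    if test in _PAIRED and len(ref) != len(cond):
        raise ValueError(f"{test} requires equal-length paired samples")
    # identical (or zero-variance identical) samples carry no evidence of a
    # difference; several scipy tests return NaN here, so fix p = 1
    if len(ref) == len(cond) and np.array_equal(np.sort(ref), np.sort(cond)):
        return 1.0
    if test == "welch_t":
        res = sps.ttest_ind(ref, cond, equal_var=False)
    elif test == "student_t":
        res = sps.ttest_ind(ref, cond, equal_var=True)
    elif test == "mann_whitney":
        res = sps.mannwhitneyu(ref, cond, alternative="two-sided")
    elif test == "paired_t":
        res = sps.ttest_rel(ref, cond)
    elif test == "wilcoxon":
        res = sps.wilcoxon(ref, cond)
    else:
        raise ValueError(f"unknown test {test!r}; choose from {TESTS}")
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def compare_to_reference(
    ref: ConditionSample,
    cond: ConditionSample,
    test: str = "welch_t",
    feature_name: str = "",
) -> ComparisonResult:
    """Two-sided test of ``cond`` against ``ref`` with Fig.-style star label."""
    p = _p_value(ref.values, cond.values, test)
    return ComparisonResult(
        feature_name=feature_name,
        condition=cond.condition,
        mean=float(np.mean(cond.values)),
        reference_mean=float(np.mean(ref.values)),
        p_value=p,
        stars=star_label(p),
    )


def holm_adjust(results: list[ComparisonResult]) -> list[ComparisonResult]:
    """Holm step-down adjustment over a family of comparisons (opt-in)."""
    m = len(results)
    order = np.argsort([r.p_value for r in results])
    adjusted = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, min(1.0, (m - rank) * results[i].p_value))
        adjusted[i] = running
    return [
        ComparisonResult(
            feature_name=r.feature_name,
            condition=r.condition,
            mean=r.mean,
            reference_mean=r.reference_mean,
            p_value=adjusted[i],
            stars=star_label(adjusted[i]),
        )
        for i, r in enumerate(results)
    ]


def feature_table(results: list[ComparisonResult]) -> pd.DataFrame:
    """Feature × condition table of group means, formatted to 4 decimals.

    The reference condition appears as the first column; modified conditions
    follow in first-appearance order. Cell values are strings ('12.3456')
    so the table round-trips through CSV unchanged.
    """
    if not results:
        raise ValueError("feature_table requires at least one result")
    features: list[str] = []
    conditions: list[str] = []
    ref_means: dict[str, float] = {}
    cells: dict[tuple[str, str], float] = {}
    for r in results:
        if r.feature_name not in features:
            features.append(r.feature_name)
        if r.condition not in conditions:
            conditions.append(r.condition)
        ref_means[r.feature_name] = r.reference_mean
        cells[(r.feature_name, r.condition)] = r.mean
    data = {
        "feature": features,
        "reference": [f"{ref_means[f]:.4f}" for f in features],
    }
    for c in conditions:
        data[c] = [
            f"{cells[(f, c)]:.4f}" if (f, c) in cells else "" for f in features
        ]
    return pd.DataFrame(data)
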