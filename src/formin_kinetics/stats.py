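"""Gated group-comparison statistics.

The decision tree applied to every comparison:

1. **Trim** — when a group's size exceeds 20, the bottom and top 2.5%
   of values (``floor(0.025 n)`` per tail) are removed before testing;
   plots keep the untrimmed data.
2. **Normality gate** — Shapiro-Wilk on each trimmed group at the gate
   level (default 0.05).
3. **Test** — both groups normal: Student's two-sample unpaired t-test;
   otherwise Mann-Whitney U.  Three or more groups: one-way ANOVA with
   post hoc Tukey HSD.
4. **Multiplicity** — pairwise comparisons use a Bonferroni-corrected
   alpha (``alpha / family_size``); the ANOVA path relies on Tukey's
   family-wise control.

The path is a pure function of the data and the plan: identical inputs
always select the same test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["StatPlan", "StatResult", "trim_outliers", "compare_two", "compare_many"]


@dataclass
class StatPlan:
    """How a family of comparisons is to be run."""

    family_size: int = 1
    alpha: float = 0.05
    trim_fraction: float = 0.025  # per tail, applied when n > trim_threshold
    trim_threshold: int = 20
    shapiro_alpha: float = 0.05
    force_test: Optional[str] = None  # {"t_two_sample_unpaired", "mann_whitney_u"}

    def __post_init__(self):
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.family_size < 1:
            raise ValueError("family_size must be >= 1")


@dataclass
class StatResult:
    comparison: str
    test_used: str
    statistic: float
    p_value: float
    alpha_corrected: float
    significant: bool
    n_trimmed_per_group: tuple = (0, 0)
    normality_p_per_group: tuple = ()

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "test_used": self.test_used,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "alpha_corrected": self.alpha_corrected,
            "significant": self.significant,
            "n_trimmed_per_group": list(self.n_trimmed_per_group),
            "normality_p_per_group": list(self.normality_p_per_group),
        }


def trim_outliers(
    sample, trim_fraction: float = 0.025, threshold: int = 20
) -> np.ndarray:
    """Symmetric tail trimming applied only to samples larger than ``threshold``.

    Removes ``k = floor(trim_fraction * n)`` smallest and largest values
    when ``n > threshold``; otherwise returns the sample unchanged.
    Note ``k`` can be zero just above the threshold (e.g. n=21 at 2.5%).
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n <= threshold:
        return x
    k = math.floor(trim_fraction * n)
    if k == 0:
        return x
    return x[k : n - k]


def _gate_and_test(a: np.ndarray, b: np.ndarray, plan: StatPlan):
    sw_a = float(sps.shapiro(a).pvalue)
    sw_b = float(sps.shapiro(b).pvalue)
    if plan.force_test is not None:
        choice = plan.force_test
    elif sw_a > plan.shapiro_alpha and sw_b > plan.shapiro_alpha:
        choice = "t_two_sample_unpaired"
    else:
        choice = "mann_whitney_u"
    if choice == "t_two_sample_unpaired":
        res = sps.ttest_ind(a, b, equal_var=True)
    elif choice == "mann_whitney_u":
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {choice!r}")
    return choice, float(res.statistic), float(res.pvalue), (sw_a, sw_b)


def compare_two(
    group_a, group_b, plan: Optional[StatPlan] = None, label: str = "A:B"
) -> StatResult:
    """Trim, gate on normality, test, and apply the corrected alpha."""
    plan = plan or StatPlan()
    a_raw = np.asarray(group_a, dtype=float)
    b_raw = np.asarray(group_b, dtype=float)
    a = trim_outliers(a_raw, plan.trim_fraction, plan.trim_threshold)
    b = trim_outliers(b_raw, plan.trim_fraction, plan.trim_threshold)
    if a.size < 3 or b.size < 3:
        raise ValueError(
            f"comparison {label!r}: need >= 3 values per group after trimming "
            f"(got {a.size} and {b.size})"
        )
    test, stat, p, sw = _gate_and_test(a, b, plan)
    alpha_c = plan.alpha / plan.family_size
    return StatResult(
        comparison=label,
        test_used=test,
        statistic=stat,
        p_value=p,
        alpha_corrected=alpha_c,
        significant=bool(p < alpha_c),
        n_trimmed_per_group=(a_raw.size - a.size, b_raw.size - b.size),
        normality_p_per_group=sw,
    )


def compare_many(groups: dict, plan: Optional[StatPlan] = None):
    """One-way ANOVA omnibus plus all-pairs Tukey HSD.

    ``groups`` maps group names to samples.  Returns the omnibus
    :class:`StatResult` followed by one result per pair with
    Tukey-adjusted p-values (compared against the plan's alpha; Tukey
    already controls the family-wise rate).
    """
    plan = plan or StatPlan()
    if len(groups) < 3:
        raise ValueError("compare_many needs >= 3 groups; use compare_two for a pair")
    names = list(groups)
    data = [trim_outliers(np.asarray(groups[k], dtype=float),
                          plan.trim_fraction, plan.trim_threshold) for k in names]
    for name, d in zip(names, data):
        if d.size < 3:
            raise ValueError(f"group {name!r}: need >= 3 values after trimming")
    f_stat, f_p = sps.f_oneway(*data)
    results = [
        StatResult(
            comparison="omnibus",
            test_used="anova_oneway",
            statistic=float(f_stat),
            p_value=float(f_p),
            alpha_corrected=plan.alpha,
            significant=bool(f_p < plan.alpha),
            n_trimmed_per_group=tuple(
                np.asarray(groups[k]).size - d.size for k, d in zip(names, data)
            ),
        )
    ]
    tukey = sps.tukey_hsd(*data)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = float(tukey.pvalue[i, j])
            results.append(
                StatResult(
                    comparison=f"{names[i]}:{names[j]}",
                    test_used="anova_tukey",
                    statistic=float(tukey.statistic[i, j]),
                    p_value=p,
                    alpha_corrected=plan.alpha,
                    significant=bool(p < plan.alpha),
                )
            )
    return results
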