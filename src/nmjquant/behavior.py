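"""Behavioral indices and the statistical decision tree with outlier screening.

The T-maze performance index averages two reciprocal conditioning runs (odor
roles swapped), which cancels any fixed arm/odor bias; 0 means no learning
(50:50 split), 1 complete learning (all flies avoid the conditioned odor).

Group comparisons follow a fixed route: D'Agostino-Pearson normality per
group; if all groups pass, an unpaired two-tailed t test (two groups) or
one-way ANOVA with Tukey's post-hoc (more); otherwise Mann-Whitney U (two
groups) or Kruskal-Wallis (more).  Outliers are screened by the iterated
two-sided single-Grubbs test at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TMazeCounts",
    "StatReport",
    "choice_index",
    "performance_index",
    "dagostino_pearson",
    "choose_and_run_test",
    "grubbs_outliers",
]


@dataclass
class TMazeCounts:
    """One reciprocal pair of T-maze runs (fly counts per arm)."""

    run1_cs_plus: int
    run1_cs_minus: int
    run2_cs_plus: int
    run2_cs_minus: int

    def __post_init__(self) -> None:
        for v in (self.run1_cs_plus, self.run1_cs_minus,
                  self.run2_cs_plus, self.run2_cs_minus):
            if v < 0:
                raise ValueError("fly counts must be non-negative")
        if self.run1_cs_plus + self.run1_cs_minus == 0:
            raise ValueError("run 1 has no flies")
        if self.run2_cs_plus + self.run2_cs_minus == 0:
            raise ValueError("run 2 has no flies")

    def performance_index(self) -> float:
        ci1 = choice_index(self.run1_cs_minus, self.run1_cs_plus)
        ci2 = choice_index(self.run2_cs_minus, self.run2_cs_plus)
        return performance_index(ci1, ci2)


def choice_index(n_avoiding: int, n_approaching: int) -> float:
    """(n_a - n_b) / (n_a + n_b), positive when the conditioned odor is avoided.

    ``n_avoiding`` is the count in the CS- arm (flies avoiding the punished
    odor), ``n_approaching`` the count in the CS+ arm.
    """
    total = n_avoiding + n_approaching
    if total <= 0:
        raise ValueError("no flies in either arm")
    return (n_avoiding - n_approaching) / total


def performance_index(index_run1: float, index_run2: float) -> float:
    """Mean of two reciprocal choice indices; fixed arm biases cancel."""
    return 0.5 * (index_run1 + index_run2)


def dagostino_pearson(values: np.ndarray) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus normality test (K^2, p).

    Combines skewness and kurtosis z-scores into K^2 ~ chi^2(2).  Requires
    n >= 8 for validity; smaller samples raise and the decision tree falls
    back to the nonparametric route.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 8:
        raise ValueError("D'Agostino-Pearson test requires n >= 8")
    k2, p = stats.normaltest(v)
    return float(k2), float(p)


@dataclass
class StatReport:
    """Record of a group comparison and the route taken to choose the test."""

    test_name: str
    statistic: float
    p_value: float
    n_per_group: dict[str, int]
    normality_p: dict[str, float]
    outliers_removed: dict[str, list] = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None


def choose_and_run_test(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
    screen_outliers: bool = False,
) -> StatReport:
    """Apply the normality-gated test decision tree to >= 2 groups.

    "Normal" requires every group to pass D'Agostino-Pearson at ``alpha``;
    groups too small for the omnibus test (n < 8) route the comparison to the
    nonparametric branch.  With ``screen_outliers`` each group is first
    Grubbs-screened at alpha = 0.05.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    data = {}
    removed = {}
    for g, v in groups.items():
        v = np.asarray(v, dtype=float)
        if v.size == 0:
            raise ValueError(f"group {g!r} is empty")
        if screen_outliers and v.size >= 3:
            v, rem = grubbs_outliers(v)
            removed[g] = list(rem)
        data[g] = v

    normality_p: dict[str, float] = {}
    all_normal = True
    for g, v in data.items():
        try:
            _, p = dagostino_pearson(v)
            normality_p[g] = p
            all_normal &= p > alpha
        except ValueError:
            normality_p[g] = float("nan")
            all_normal = False

    samples = list(data.values())
    posthoc = None
    if all_normal and len(data) == 2:
        test_name = "unpaired two-tailed t test"
        stat, p = stats.ttest_ind(*samples)
    elif all_normal:
        test_name = "one-way ANOVA + Tukey HSD"
        stat, p = stats.f_oneway(*samples)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        flat = np.concatenate(samples)
        labels = np.concatenate([[g] * len(v) for g, v in data.items()])
        tk = pairwise_tukeyhsd(flat, labels, alpha=alpha)
        posthoc = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
    elif len(data) == 2:
        test_name = "Mann-Whitney U test"
        stat, p = stats.mannwhitneyu(*samples, alternative="two-sided")
    else:
        test_name = "Kruskal-Wallis test"
        stat, p = stats.kruskal(*samples)

    return StatReport(
        test_name=test_name,
        statistic=float(stat),
        p_value=float(p),
        n_per_group={g: len(v) for g, v in data.items()},
        normality_p=normality_p,
        outliers_removed=removed,
        posthoc=posthoc,
    )


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value G_crit for a single outlier."""
    t2 = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2) ** 2
    return (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))


def grubbs_outliers(
    values: np.ndarray,
    alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterated two-sided single-Grubbs outlier removal.

    At each pass the single most extreme point is tested against the Grubbs
    critical value at ``alpha``; if significant it is removed and the test
    repeats, stopping when no point is significant or fewer than 3 values
    remain.  Returns ``(clean, removed)``; removal order does not depend on
    the input ordering.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("Grubbs test requires at least 3 values")
    removed = []
    while v.size >= 3:
        mean, sd = v.mean(), v.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(v - mean)
        i = int(np.argmax(dev))
        g = dev[i] / sd
        if g > grubbs_critical(v.size, alpha):
            removed.append(v[i])
            v = np.delete(v, i)
        else:
            break
    return v, np.asarray(removed)
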