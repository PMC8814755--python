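"""Cohort-level statistics on per-cell phenotype tables.

Two-sample Student t-tests (pooled variance; Welch behind a flag) at
alpha = 0.05, Tukey-Kramer all-pairs comparisons for >= 3 groups, optional
Bonferroni correction for planned multiple t-tests, notched-boxplot
summaries (notch = median +/- 1.57 * IQR / sqrt(n), the 95% CI of the
median), and post-hoc power from the noncentral-t distribution, including
the minimum effect size needed to reach power 0.80.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

__all__ = [
    "ComparisonResult",
    "BoxSummary",
    "compare_two",
    "tukey_all_pairs",
    "posthoc_power",
    "power_two_sample_t",
    "min_effect_for_power",
    "notched_summary",
    "compare_groups",
    "comparisons_frame",
    "power_report",
]

POWER_TARGET = 0.80


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    metric: str
    statistic: float
    p_value: float
    adjusted: str  # none | tukey | bonferroni
    significant: bool
    alpha: float
    effect_size: float  # Cohen's d, (mean_a - mean_b) / pooled sd
    power: float
    min_effect_for_power80: float
    n_a: int = 0
    n_b: int = 0
    degenerate: bool = False


@dataclass(frozen=True)
class BoxSummary:
    median: float
    q1: float
    q3: float
    notch_low: float
    notch_high: float
    n: int


def power_two_sample_t(
    effect_size: float, n_a: int, n_b: int, alpha: float = 0.05
) -> float:
    """Power of the two-sided two-sample pooled t-test at Cohen's d
    ``effect_size``, from the noncentral t distribution."""
    df = n_a + n_b - 2
    ncp = abs(effect_size) * np.sqrt(n_a * n_b / (n_a + n_b))
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    if ncp > tcrit + 40.0:  # beyond float resolution: power is 1
        return 1.0
    upper = sps.nct.cdf(tcrit, df, ncp)
    lower = sps.nct.cdf(-tcrit, df, ncp)
    # scipy's nct.cdf underflows to NaN deep in a tail; those terms are 0
    if not np.isfinite(upper):
        upper = 0.0
    if not np.isfinite(lower):
        lower = 0.0
    return float(1.0 - upper + lower)


@lru_cache(maxsize=1024)
def min_effect_for_power(
    n_a: int, n_b: int, alpha: float = 0.05, target: float = POWER_TARGET
) -> float:
    """Smallest |d| reaching the target power, by bracketed root finding."""
    return float(
        brentq(
            lambda d: power_two_sample_t(d, n_a, n_b, alpha) - target,
            1e-9,
            50.0,
            xtol=1e-12,
        )
    )


def posthoc_power(
    effect_size: float, n_a: int, n_b: int, alpha: float = 0.05
) -> tuple[float, float]:
    """(power at the observed effect size, minimum effect for power 0.80)."""
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    return (
        power_two_sample_t(effect_size, n_a, n_b, alpha),
        min_effect_for_power(n_a, n_b, alpha),
    )


def _cohens_d(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    sp = np.sqrt(sp2)
    diff = a.mean() - b.mean()
    return (diff / sp if sp > 0 else np.inf * np.sign(diff) if diff else 0.0, sp)


def compare_two(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    metric: str = "",
    labels: tuple[str, str] = ("a", "b"),
    welch: bool = False,
) -> ComparisonResult:
    """Two-sample Student t-test (pooled variance) with effect size and
    post-hoc power. Zero pooled variance with equal means gives p = 1;
    with unequal means the result is flagged degenerate (p = 0)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    d, sp = _cohens_d(a, b)
    degenerate = sp == 0.0
    if degenerate:
        if a.mean() == b.mean():
            stat, p = 0.0, 1.0
        else:
            stat, p = np.inf * np.sign(a.mean() - b.mean()), 0.0
    else:
        stat, p = sps.ttest_ind(a, b, equal_var=not welch)
        stat, p = float(stat), float(p)
    power, min_eff = posthoc_power(0.0 if degenerate else d, a.size, b.size, alpha)
    return ComparisonResult(
        group_a=labels[0],
        group_b=labels[1],
        metric=metric,
        statistic=stat,
        p_value=p,
        adjusted="none",
        significant=p < alpha,
        alpha=alpha,
        effect_size=float(d) if np.isfinite(d) else d,
        power=power,
        min_effect_for_power80=min_eff,
        n_a=int(a.size),
        n_b=int(b.size),
        degenerate=bool(degenerate),
    )


def tukey_all_pairs(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    metric: str = "",
) -> list[ComparisonResult]:
    """Tukey-Kramer simultaneous all-pairs comparisons (family-wise error
    controlled at alpha). With exactly two groups this delegates to
    :func:`compare_two`."""
    names = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    for name, arr in zip(names, arrays):
        if arr.size < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
    if len(names) < 2:
        raise ValueError("at least two groups are required")
    if len(names) == 2:
        return [
            compare_two(arrays[0], arrays[1], alpha, metric, (names[0], names[1]))
        ]
    res = sps.tukey_hsd(*arrays)
    out: list[ComparisonResult] = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = arrays[i], arrays[j]
            d, _ = _cohens_d(a, b)
            p = float(res.pvalue[i, j])
            power, min_eff = posthoc_power(d, a.size, b.size, alpha)
            out.append(
                ComparisonResult(
                    group_a=names[i],
                    group_b=names[j],
                    metric=metric,
                    statistic=float(res.statistic[i, j]),
                    p_value=p,
                    adjusted="tukey",
                    significant=p < alpha,
                    alpha=alpha,
                    effect_size=float(d) if np.isfinite(d) else d,
                    power=power,
                    min_effect_for_power80=min_eff,
                    n_a=int(a.size),
                    n_b=int(b.size),
                )
            )
    return out


def notched_summary(values: Sequence[float]) -> BoxSummary:
    """Notched-boxplot summary: quartiles by linear interpolation and
    notch = median +/- 1.57 * IQR / sqrt(n) (McGill's 95% CI of the median)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need n >= 2 values")
    median = float(np.median(v))
    q1, q3 = (float(q) for q in np.percentile(v, [25, 75]))
    half = 1.57 * (q3 - q1) / np.sqrt(v.size)
    return BoxSummary(median, q1, q3, median - half, median + half, int(v.size))


def compare_groups(
    table: pd.DataFrame,
    metrics: Sequence[str],
    group_col: str = "group",
    alpha: float = 0.05,
    adjustment: str = "auto",
) -> list[ComparisonResult]:
    """Run the analysis plan on a long features table: per metric, a t-test
    for two groups or Tukey-Kramer for more. ``adjustment='bonferroni'``
    divides alpha by the number of planned t-tests (multiple planned
    comparisons of two groups)."""
    results: list[ComparisonResult] = []
    names = sorted(table[group_col].unique())
    for metric in metrics:
        groups = {
            g: table.loc[table[group_col] == g, metric].dropna().to_numpy()
            for g in names
        }
        if len(names) == 2 and adjustment in ("auto", "none", "bonferroni"):
            r = compare_two(
                groups[names[0]], groups[names[1]], alpha, metric,
                (names[0], names[1]),
            )
            results.append(r)
        else:
            results.extend(tukey_all_pairs(groups, alpha, metric))
    if adjustment == "bonferroni":
        planned = [r for r in results if r.adjusted == "none"]
        m = len(planned)
        if m > 1:
            alpha_eff = alpha / m
            results = [
                (
                    ComparisonResult(
                        **{
                            **r.__dict__,
                            "adjusted": "bonferroni",
                            "alpha": alpha_eff,
                            "significant": r.p_value < alpha_eff,
                        }
                    )
                    if r.adjusted == "none"
                    else r
                )
                for r in results
            ]
    return results


def comparisons_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_a": r.group_a,
                "group_b": r.group_b,
                "metric": r.metric,
                "n_a": r.n_a,
                "n_b": r.n_b,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "adjusted": r.adjusted,
                "alpha": r.alpha,
                "significant": r.significant,
                "effect_size": r.effect_size,
            }
            for r in results
        ]
    )


def power_report(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Power table mirroring the per-test post-hoc power summary: observed
    effect size, achieved power, and (when power < 0.80) the minimum effect
    size needed to reach 0.80."""
    rows = []
    for i, r in enumerate(results):
        rows.append(
            {
                "test_id": i,
                "group_a": r.group_a,
                "group_b": r.group_b,
                "metric": r.metric,
                "n_a": r.n_a,
                "n_b": r.n_b,
                "effect_size": r.effect_size,
                "power": r.power,
                "min_effect_for_power80": (
                    r.min_effect_for_power80 if r.power < POWER_TARGET else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)
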