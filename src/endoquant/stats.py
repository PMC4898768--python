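"""Hierarchical aggregation and hypothesis testing.

The statistical unit is the **independent experiment**, not the cell:
per-cell measurements are first averaged within each (condition,
experiment) to give experiment means, and the condition mean +/- SEM and
every test are computed across those experiment means.  Pooling cells
directly would overstate the effective sample size, since cells within an
experiment share culture, staining and imaging conditions.

Tests follow the conventions of the quantification workflow this package
reproduces: one-way ANOVA with the Newman-Keuls (student-Newman-Keuls)
stepwise studentized-range post test for >= 3 conditions, a pooled-variance
two-sample Student's t test for 2, both two-sided at alpha = 0.05 by
default.  Effect sizes are reported as percent change and fold change with
delta-method uncertainties.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ExperimentSummary",
    "ConditionSummary",
    "aggregate",
    "one_way_anova",
    "newman_keuls",
    "students_t",
    "effect_size",
]


@dataclass(frozen=True)
class ExperimentSummary:
    experiment_id: str
    condition: str
    mean: float
    n_cells: int


@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    mean: float
    sem: float
    n_experiments: int


def aggregate(
    measurements: pd.DataFrame, value: str = "net_mean"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cells -> experiment means -> condition mean +/- SEM.

    ``measurements`` must carry ``condition`` and ``experiment_id`` labels
    and the value column.  Returns ``(experiment_table, condition_table)``;
    the condition SEM is computed across experiment means (NaN when a
    condition has a single experiment — tests are refused at that depth,
    but the summary is still produced).
    """
    required = {"condition", "experiment_id", value}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements missing columns: {sorted(missing)}")
    if measurements[["condition", "experiment_id"]].isna().any().any():
        raise ValueError("condition/experiment_id labels must not be missing")
    exp = (
        measurements.groupby(["condition", "experiment_id"], sort=True)[value]
        .agg(mean="mean", n_cells="count")
        .reset_index()
    )
    cond = (
        exp.groupby("condition", sort=True)["mean"]
        .agg(
            mean="mean",
            sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
            n_experiments="count",
        )
        .reset_index()
    )
    return exp, cond


def _as_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    if len(out) < 2:
        raise ValueError("need >= 2 groups")
    for g in out:
        if g.size < 2:
            raise ValueError("every group needs >= 2 values "
                             "(>= 2 independent experiments per condition)")
    return out


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA.

    F = MS_between / MS_within with (k - 1, N - k) degrees of freedom; the
    p value comes from the F distribution.  Zero within-group variance with
    equal group means leaves F undefined (NaN, NaN).
    """
    gs = _as_groups(groups)
    k = len(gs)
    n_total = sum(g.size for g in gs)
    grand = np.concatenate(gs).mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return float("nan"), float("nan")
        return float("inf"), 0.0
    f = (ss_between / df_b) / (ss_within / df_w)
    return float(f), float(sps.f.sf(f, df_b, df_w))


def _anova_mse(gs: list[np.ndarray]) -> tuple[float, int]:
    df_w = sum(g.size for g in gs) - len(gs)
    ss_w = sum(((g - g.mean()) ** 2).sum() for g in gs)
    return ss_w / df_w, df_w


@lru_cache(maxsize=4096)
def _q_critical(alpha: float, r: int, df: int) -> float:
    """Upper studentized-range quantile q(1 - alpha; r, df), cached because
    the numerical quantile inversion is costly and Newman-Keuls revisits the
    same (alpha, r, df) triples constantly."""
    return float(sps.studentized_range.ppf(1.0 - alpha, r, df))


def newman_keuls(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Student-Newman-Keuls stepwise studentized-range post test.

    Group means are ordered; a pair whose ordered positions span ``r``
    means is tested against the studentized-range critical value
    ``q(1 - alpha; r, df_within)`` with the ANOVA within-group mean square
    as the variance estimate (harmonic mean of the two group sizes for
    unequal n).  Testing proceeds from the widest stretch inward, and a
    non-significant stretch blocks every pair it contains.

    Returns a symmetric boolean DataFrame of pairwise significance.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    gs = _as_groups(groups)
    k = len(gs)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels length must match number of groups")
    mse, df_w = _anova_mse(gs)
    means = np.array([g.mean() for g in gs])
    ns = np.array([g.size for g in gs])
    order = np.argsort(means, kind="stable")

    sig = np.zeros((k, k), dtype=bool)
    blocked = np.zeros((k, k), dtype=bool)  # indexed by ordered positions
    for r in range(k, 1, -1):
        for i in range(0, k - r + 1):
            j = i + r - 1
            a, b = order[i], order[j]
            if blocked[i, j]:
                continue
            if mse == 0.0:
                significant = means[b] != means[a]
            else:
                n_h = 2.0 / (1.0 / ns[a] + 1.0 / ns[b])
                q = (means[b] - means[a]) / np.sqrt(mse / n_h)
                significant = bool(q > _q_critical(alpha, r, df_w))
            if significant:
                sig[a, b] = sig[b, a] = True
            else:
                # block every pair inside this stretch
                for ii in range(i, j + 1):
                    for jj in range(ii + 1, j + 1):
                        blocked[ii, jj] = True
    return pd.DataFrame(sig, index=list(labels), columns=list(labels))


def students_t(
    group1: Sequence[float], group2: Sequence[float], welch: bool = False
) -> tuple[float, float]:
    """Two-sample Student's t test (pooled variance by default; Welch
    behind a flag), two-sided p.

    Zero variance in both groups with equal means leaves the statistic
    undefined (NaN, NaN).
    """
    g1, g2 = _as_groups([group1, group2])
    if g1.std(ddof=1) == 0 and g2.std(ddof=1) == 0:
        if g1.mean() == g2.mean():
            return float("nan"), float("nan")
        return float("inf") * np.sign(g1.mean() - g2.mean()), 0.0
    res = sps.ttest_ind(g1, g2, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def effect_size(
    control_mean: float,
    treated_mean: float,
    control_sem: float = float("nan"),
    treated_sem: float = float("nan"),
) -> dict[str, float]:
    """Percent change and fold change of treated vs control.

    percent = 100 * (treated - control) / control; fold = treated / control.
    Uncertainties propagate the experiment-level SEMs to first order
    (delta method): SE(fold) = |fold| * sqrt((SE_T/T)^2 + (SE_C/C)^2).
    """
    if control_mean == 0:
        raise ZeroDivisionError("control mean is zero; effect size undefined")
    fold = treated_mean / control_mean
    percent = 100.0 * (treated_mean - control_mean) / control_mean
    rel = 0.0
    if np.isfinite(treated_sem) and treated_mean != 0:
        rel += (treated_sem / treated_mean) ** 2
    if np.isfinite(control_sem):
        rel += (control_sem / control_mean) ** 2
    fold_se = abs(fold) * np.sqrt(rel) if rel > 0 else float("nan")
    return {
        "percent_change": float(percent),
        "percent_change_se": float(100.0 * fold_se) if np.isfinite(fold_se) else float("nan"),
        "fold_change": float(fold),
        "fold_change_se": float(fold_se) if np.isfinite(fold_se) else float("nan"),
    }
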