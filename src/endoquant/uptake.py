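"""Fluid-phase uptake time-course analysis.

Uptake assays (intracellular HRP absorbance, FITC-dextran fluorescence)
accumulate probe approximately linearly with incubation time.  This module
fits that accumulation by ordinary least squares, compares conditions at
each shared timepoint with the package's hierarchical statistics (the
independent experiment is the unit of replication), and reports
treated/control fold changes with delta-method standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as _stats

__all__ = [
    "UptakeSeries",
    "AccumulationFit",
    "fit_linear_accumulation",
    "fold_change_at_time",
    "per_timepoint_comparison",
]

_COLUMNS = ("condition", "experiment_id", "time_min", "replicate", "readout")


@dataclass(frozen=True)
class UptakeSeries:
    """Replicate readouts of one condition over timepoints (long format)."""

    condition: str
    data: pd.DataFrame  # columns: experiment_id, time_min, replicate, readout

    def __post_init__(self) -> None:
        missing = {"time_min", "readout"} - set(self.data.columns)
        if missing:
            raise ValueError(f"uptake table missing columns: {sorted(missing)}")
        if self.data["time_min"].nunique() < 2:
            raise ValueError("an uptake series needs at least 2 timepoints")
        if not np.isfinite(self.data["readout"].to_numpy(float)).all():
            raise ValueError("readouts must be finite")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, condition: str | None = None) -> "UptakeSeries":
        if condition is not None:
            frame = frame[frame["condition"] == condition]
        else:
            conds = frame["condition"].unique()
            if len(conds) != 1:
                raise ValueError("frame holds multiple conditions; pass one explicitly")
            condition = conds[0]
        return cls(condition=str(condition), data=frame.reset_index(drop=True))

    def timepoints(self) -> np.ndarray:
        return np.sort(self.data["time_min"].unique())

    def at_time(self, t: float) -> np.ndarray:
        sel = self.data[np.isclose(self.data["time_min"], t)]
        return sel["readout"].to_numpy(float)

    def mean_sem(self, t: float) -> tuple[float, float, int]:
        v = self.at_time(t)
        n = v.size
        sem = float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
        return float(v.mean()), sem, n


@dataclass(frozen=True)
class AccumulationFit:
    """OLS line through all replicate points of a series."""

    condition: str
    slope: float           # readout units / min
    intercept: float       # readout units
    slope_se: float
    r_squared: float
    per_timepoint: pd.DataFrame  # time_min, mean, sem, n


def fit_linear_accumulation(series: UptakeSeries) -> AccumulationFit:
    """Ordinary least-squares accumulation fit over all replicate points.

    The t = 0 baseline is retained (not subtracted) so the intercept
    absorbs any assay blank.  Exact on noiseless linear data.
    """
    t = series.data["time_min"].to_numpy(float)
    y = series.data["readout"].to_numpy(float)
    if np.unique(t).size < 2:
        raise ValueError("need readouts at >= 2 distinct timepoints")
    res = sps.linregress(t, y)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    per_tp = (
        series.data.groupby("time_min")["readout"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    per_tp["sem"] = per_tp["sd"] / np.sqrt(per_tp["n"])
    return AccumulationFit(
        condition=series.condition,
        slope=float(res.slope), intercept=float(res.intercept),
        slope_se=float(res.stderr), r_squared=r2,
        per_timepoint=per_tp[["time_min", "mean", "sem", "n"]],
    )


def fold_change_at_time(
    treated: UptakeSeries, control: UptakeSeries, t: float
) -> tuple[float, float]:
    """Treated/control ratio of replicate means at timepoint ``t``.

    The standard error comes from first-order (delta-method) propagation of
    the two SEMs: ``SE(f) = f * sqrt((SE_T/T)^2 + (SE_C/C)^2)``.  A zero
    control mean leaves the fold undefined (returned as NaN).
    """
    for s in (treated, control):
        if not np.any(np.isclose(s.timepoints(), t)):
            raise ValueError(f"timepoint {t} absent from condition {s.condition!r}")
    mt, st, _ = treated.mean_sem(t)
    mc, sc, _ = control.mean_sem(t)
    if mc == 0:
        return float("nan"), float("nan")
    fold = mt / mc
    rel = 0.0
    if np.isfinite(st) and mt != 0:
        rel += (st / mt) ** 2
    if np.isfinite(sc):
        rel += (sc / mc) ** 2
    return float(fold), float(abs(fold) * np.sqrt(rel))


def per_timepoint_comparison(
    series: dict[str, UptakeSeries],
    control: str = "control",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare each treated condition with the control at every shared
    timepoint, mirroring figure-legend semantics ("p < 0.05 relative to the
    corresponding timepoint of the control condition").

    Two conditions are compared with a pooled two-sample t test; three or
    more with one-way ANOVA followed by the Newman-Keuls post test, and the
    reported pairwise flag is the Newman-Keuls decision for (condition,
    control).  Timepoints where every condition is constant and equal
    (e.g. the t = 0 blank) are reported as not significant with NaN p.
    """
    if control not in series:
        raise KeyError(f"control condition {control!r} missing")
    if len(series) < 2:
        raise ValueError("need >= 2 conditions")
    shared = None
    for s in series.values():
        tp = set(np.round(s.timepoints(), 9))
        shared = tp if shared is None else shared & tp
    treated_names = [c for c in series if c != control]
    rows = []
    for t in sorted(shared):
        groups = {name: s.at_time(t) for name, s in series.items()}
        values = list(groups.values())
        degenerate = all(np.ptp(v) == 0 for v in values) and \
            np.ptp([v[0] for v in values]) == 0
        if degenerate:
            for name in treated_names:
                fold, fold_se = fold_change_at_time(series[name], series[control], t)
                rows.append({"time_min": t, "condition": name, "p": float("nan"),
                             "significant": False, "fold_vs_control": fold,
                             "fold_se": fold_se, "test": "degenerate"})
            continue
        if len(series) == 2:
            name = treated_names[0]
            t_stat, p = _stats.students_t(groups[name], groups[control])
            fold, fold_se = fold_change_at_time(series[name], series[control], t)
            rows.append({"time_min": t, "condition": name, "p": p,
                         "significant": bool(p < alpha), "fold_vs_control": fold,
                         "fold_se": fold_se, "test": "t"})
        else:
            labels = list(groups)
            _, p_anova = _stats.one_way_anova(list(groups.values()))
            nk = _stats.newman_keuls(list(groups.values()), alpha=alpha, labels=labels)
            for name in treated_names:
                sig = bool(p_anova < alpha) and bool(nk.loc[name, control])
                fold, fold_se = fold_change_at_time(series[name], series[control], t)
                rows.append({"time_min": t, "condition": name, "p": p_anova,
                             "significant": sig, "fold_vs_control": fold,
                             "fold_se": fold_se, "test": "anova+nk"})
    return pd.DataFrame(rows)
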