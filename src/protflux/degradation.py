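"""In vitro degradation statistics for the Ub-Sic1 proteasome assay.

Each time course records the loading-normalized substrate band at 0, 5 and
15 minutes for one replicate of one proteasome:peptide molar-ratio
condition.  Inhibition is quantified by the per-replicate drop statistics

    delta_0_5  = signal(0) - signal(5)
    delta_0_15 = signal(0) - signal(15),

compared across conditions with a one-way ANOVA and pairwise contrasts
against the uninhibited (1:0) group, Holm-adjusted.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import DegradationRecord

__all__ = ["DegradationCourse", "DeltaStats", "courses_from_records",
           "degradation_deltas"]

EXPECTED_TIMEPOINTS = (0.0, 5.0, 15.0)


@dataclass
class DegradationCourse:
    """One replicate's normalized time course at 0/5/15 minutes."""

    condition: str
    replicate_id: str
    signal: dict  # time_min -> normalized intensity

    def __post_init__(self) -> None:
        times = tuple(sorted(self.signal))
        if times != EXPECTED_TIMEPOINTS:
            raise ValueError(
                f"timepoints must be exactly {EXPECTED_TIMEPOINTS}, got {times}"
            )
        if any(v <= 0 for v in self.signal.values()):
            raise ValueError("normalized signals must be > 0")

    @property
    def delta_0_5(self) -> float:
        return self.signal[0.0] - self.signal[5.0]

    @property
    def delta_0_15(self) -> float:
        return self.signal[0.0] - self.signal[15.0]


def courses_from_records(records: Sequence[DegradationRecord]) -> list[DegradationCourse]:
    """Assemble per-replicate courses from band records (target/loading)."""
    grouped: dict[tuple[str, str], dict] = {}
    for rec in records:
        grouped.setdefault((rec.condition, rec.replicate_id), {})[rec.time_min] = (
            rec.normalized
        )
    return [
        DegradationCourse(condition=cond, replicate_id=rep, signal=sig)
        for (cond, rep), sig in sorted(grouped.items())
    ]


@dataclass
class DeltaStats:
    """Group summaries, ANOVA and post hoc contrasts of the drop statistics."""

    per_replicate: pd.DataFrame  # condition, replicate_id, delta_0_5, delta_0_15
    group_means: pd.DataFrame  # per condition: mean and SE of both deltas
    anova: dict  # {"delta_0_5": {"F", "p", "df"}, "delta_0_15": {...}}
    posthoc: pd.DataFrame  # contrasts vs baseline, Holm-adjusted
    baseline: str

    def summary(self) -> str:
        lines = ["Degradation drop statistics", "=" * 44]
        for stat in ("delta_0_5", "delta_0_15"):
            a = self.anova[stat]
            lines.append(
                f"{stat}: F({a['df'][0]},{a['df'][1]}) = {a['F']:.4g}, p = {a['p']:.4g}"
            )
        lines.append("group means (mean +/- SE):")
        for cond, row in self.group_means.iterrows():
            lines.append(
                f"  {cond}: d0-5 {row['delta_0_5_mean']:.4g} +/- {row['delta_0_5_se']:.2g}, "
                f"d0-15 {row['delta_0_15_mean']:.4g} +/- {row['delta_0_15_se']:.2g}"
            )
        if len(self.posthoc):
            lines.append(f"post hoc vs {self.baseline} (Holm):")
            for _, row in self.posthoc.iterrows():
                lines.append(
                    f"  {row['statistic']} {row['condition']}: p_adj = {row['p_adj']:.4g}"
                )
        return "\n".join(lines)


def degradation_deltas(
    courses: Sequence[DegradationCourse], baseline: str = "1:0"
) -> DeltaStats:
    """Compute drop statistics, one-way ANOVA and Holm-adjusted contrasts.

    Requires >= 2 replicates per condition.  Pairwise contrasts compare
    each non-baseline condition against ``baseline`` with two-sided t
    tests, Holm-adjusted within each delta statistic.
    """
    if not courses:
        raise ValueError("no degradation courses")
    df = pd.DataFrame(
        {
            "condition": c.condition,
            "replicate_id": c.replicate_id,
            "delta_0_5": c.delta_0_5,
            "delta_0_15": c.delta_0_15,
        }
        for c in courses
    )
    counts = df.groupby("condition").size()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"need >= 2 replicates per condition; too few in {small}")

    conditions = sorted(df["condition"].unique())
    n_groups = len(conditions)
    n_total = len(df)

    anova = {}
    for stat in ("delta_0_5", "delta_0_15"):
        groups = [df.loc[df.condition == c, stat].to_numpy() for c in conditions]
        if n_groups >= 2:
            f_res = stats.f_oneway(*groups)
            F, p = float(f_res.statistic), float(f_res.pvalue)
            if not np.isfinite(F):  # all values identical across groups
                F, p = 0.0, 1.0
        else:
            F, p = 0.0, 1.0
        anova[stat] = {"F": F, "p": p, "df": (n_groups - 1, n_total - n_groups)}

    gm = df.groupby("condition").agg(
        delta_0_5_mean=("delta_0_5", "mean"),
        delta_0_5_se=("delta_0_5", "sem"),
        delta_0_15_mean=("delta_0_15", "mean"),
        delta_0_15_se=("delta_0_15", "sem"),
        n=("delta_0_5", "size"),
    )

    rows = []
    others = [c for c in conditions if c != baseline]
    if baseline in conditions and others:
        base = df[df.condition == baseline]
        for stat in ("delta_0_5", "delta_0_15"):
            pvals = []
            for cond in others:
                t_res = stats.ttest_ind(
                    df.loc[df.condition == cond, stat],
                    base[stat],
                    equal_var=True,
                )
                pvals.append(float(t_res.pvalue) if np.isfinite(t_res.pvalue) else 1.0)
            adj = multipletests(pvals, method="holm")[1]
            for cond, p_raw, p_adj in zip(others, pvals, adj):
                rows.append(
                    {"statistic": stat, "condition": cond,
                     "p_raw": p_raw, "p_adj": float(p_adj)}
                )
    posthoc = pd.DataFrame(rows, columns=["statistic", "condition", "p_raw", "p_adj"])

    return DeltaStats(
        per_replicate=df, group_means=gm, anova=anova, posthoc=posthoc,
        baseline=baseline,
    )
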