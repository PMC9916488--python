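"""Cohort aggregation and group statistics.

Per-animal metrics (mean-of-three-cycles P_max, P_thresh, V_filling, v-shape
percentage, bladder-to-bodyweight ratio) are aggregated into group-by-week
mean +/- SD tables, compared cross-sectionally with unpaired (Welch) t-tests
against the sham group and longitudinally with one-way repeated-measures
ANOVA (subject as block) plus Bonferroni-corrected post-hoc pairwise tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "AnimalWeek",
    "bladder_bodyweight_ratio",
    "group_summary",
    "compare_groups",
    "bonferroni",
    "percent_of_animals",
]


@dataclass
class AnimalWeek:
    """Per-animal, per-week metric record (week 0 = baseline)."""

    animal_id: str
    group: str
    week: int
    pmax_cmH2O: float = math.nan
    pthresh_cmH2O: float = math.nan
    v_filling_ul: float = math.nan
    vshape_pct: float | None = None
    bodyweight_g: list[float] | None = None
    bladder_weight_mg: float | None = None

    def __post_init__(self) -> None:
        if self.week < 0:
            raise ValidationError("week index must be >= 0 (0 = baseline)")


def bladder_bodyweight_ratio(
    bladder_weight_mg: float, last_three_bodyweights_g: Sequence[float]
) -> float:
    """Bladder weight over the mean of the last three daily bodyweights (mg/g)."""
    if len(last_three_bodyweights_g) != 3:
        raise ValidationError("exactly three bodyweights are required")
    if any(w <= 0 for w in last_three_bodyweights_g):
        raise ValidationError("bodyweights must be positive")
    if bladder_weight_mg < 0:
        raise ValidationError("bladder weight must be nonnegative")
    return bladder_weight_mg / (sum(last_three_bodyweights_g) / 3.0)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([vars(r) for r in records])


def group_summary(records, metric: str) -> pd.DataFrame:
    """Per-(group, week) n, mean and sample SD of ``metric``.

    Sample SD uses the n-1 divisor; a single record reports SD 0 with an
    ``n1_flag``.
    """
    frame = _as_frame(records)
    rows = []
    for (group, week), sub in frame.groupby(["group", "week"], sort=True):
        vals = sub[metric].astype(float).dropna().to_numpy()
        if vals.size == 0:
            continue
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        rows.append(
            {
                "group": group,
                "week": week,
                "metric": metric,
                "n": int(vals.size),
                "mean": float(vals.mean()),
                "sd": sd,
                "n1_flag": vals.size == 1,
            }
        )
    return pd.DataFrame(rows)


def bonferroni(p: float, n_comparisons: int) -> float:
    """Bonferroni-adjusted p-value, capped at 1."""
    return min(1.0, p * n_comparisons)


def _welch_rows(frame: pd.DataFrame, metric: str, week: int, reference: str,
                welch: bool) -> list[dict]:
    at_week = frame[frame["week"] == week]
    ref_vals = at_week.loc[at_week["group"] == reference, metric].dropna()
    rows = []
    others = sorted(g for g in at_week["group"].unique() if g != reference)
    for grp in others:
        vals = at_week.loc[at_week["group"] == grp, metric].dropna()
        res = stats.ttest_ind(vals, ref_vals, equal_var=not welch)
        rows.append(
            {
                "contrast": f"{grp} vs {reference} @ week {week}",
                "test": "welch_t" if welch else "student_t",
                "p": float(res.pvalue),
                "p_bonferroni": bonferroni(float(res.pvalue), len(others)),
            }
        )
    return rows


def _rm_anova_rows(frame: pd.DataFrame, metric: str, group: str) -> list[dict]:
    from statsmodels.stats.anova import AnovaRM

    sub = frame.loc[frame["group"] == group, ["animal_id", "week", metric]].dropna()
    counts = sub.groupby("animal_id")["week"].nunique()
    n_weeks = sub["week"].nunique()
    complete = counts[counts == n_weeks].index
    if len(complete) < len(counts):
        warnings.warn(
            f"{len(counts) - len(complete)} subject(s) dropped for missing weeks",
            stacklevel=3,
        )
    sub = sub[sub["animal_id"].isin(complete)]
    res = AnovaRM(sub, depvar=metric, subject="animal_id", within=["week"]).fit()
    p_time = float(res.anova_table["Pr > F"].iloc[0])
    rows = [
        {
            "contrast": f"{group}: week effect (RM-ANOVA)",
            "test": "rm_anova_F",
            "p": p_time,
            "p_bonferroni": p_time,
        }
    ]
    weeks = sorted(sub["week"].unique())
    pairs = [(a, b) for i, a in enumerate(weeks) for b in weeks[i + 1 :]]
    wide = sub.pivot(index="animal_id", columns="week", values=metric)
    for a, b in pairs:
        res_t = stats.ttest_rel(wide[a], wide[b])
        rows.append(
            {
                "contrast": f"{group}: week {a} vs week {b}",
                "test": "paired_t",
                "p": float(res_t.pvalue),
                "p_bonferroni": bonferroni(float(res_t.pvalue), len(pairs)),
            }
        )
    return rows


def compare_groups(records, design: dict) -> pd.DataFrame:
    """Run the group comparisons named by ``design``.

    ``design`` keys:

    * ``kind`` — ``"cross_sectional"`` (each group vs the reference at one
      week, unpaired t-test) or ``"within_group"`` (one-way repeated-measures
      ANOVA on week with subject as block, Bonferroni post hoc).
    * ``metric`` — column to compare.
    * ``week`` (cross-sectional) / ``group`` (within-group).
    * ``reference`` — reference group label, default ``"sham"``.
    * ``welch`` — use the Welch correction (default True).
    """
    frame = _as_frame(records)
    kind = design.get("kind")
    metric = design.get("metric")
    if metric is None or metric not in frame.columns:
        raise ConfigurationError(f"unknown metric {metric!r}")
    if kind == "cross_sectional":
        rows = _welch_rows(
            frame,
            metric,
            week=design["week"],
            reference=design.get("reference", "sham"),
            welch=design.get("welch", True),
        )
    elif kind == "within_group":
        rows = _rm_anova_rows(frame, metric, group=design["group"])
    else:
        raise ConfigurationError(f"unknown design kind {kind!r}")
    return pd.DataFrame(rows)


def percent_of_animals(count: int, total: int) -> int:
    """Integer percentage ``round(100*count/total)`` with half-up rounding."""
    if total <= 0:
        raise ValidationError("total must be positive")
    if not 0 <= count <= total:
        raise ValidationError("need 0 <= count <= total")
    return int(math.floor(100.0 * count / total + 0.5))
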