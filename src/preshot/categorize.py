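"""MAP-quadrant categorization of trials from score and perceived control.

Each trial is crossed on two margins: performance level (optimal iff
score ≥ score threshold) and action control (automatic iff control ≤
control threshold), yielding Type 1 optimal-automatic, Type 2
optimal-controlled, Type 3 suboptimal-controlled, Type 4
suboptimal-automatic. Thresholds are either the study's fixed cut-offs
(10.2 score, 4 Borg units) or data-driven medians (median-split mode,
pooled across subjects by default with a per-subject option).
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np
import pandas as pd

from .errors import DesignError, ValidationError
from .io import SCORE_RANGE, CONTROL_RANGE


class PerformanceType(enum.IntEnum):
    TYPE1_OPTIMAL_AUTOMATIC = 1
    TYPE2_OPTIMAL_CONTROLLED = 2
    TYPE3_SUBOPTIMAL_CONTROLLED = 3
    TYPE4_SUBOPTIMAL_AUTOMATIC = 4


@dataclasses.dataclass(frozen=True)
class QuadrantRule:
    score_threshold: float = 10.2
    control_threshold: float = 4.0
    mode: str = "fixed"

    def __post_init__(self):
        if not SCORE_RANGE[0] <= self.score_threshold <= SCORE_RANGE[1]:
            raise ValidationError("score threshold outside the 0–10.9 scale")
        if not CONTROL_RANGE[0] <= self.control_threshold <= CONTROL_RANGE[1]:
            raise ValidationError("control threshold outside the 0–11 scale")


def derive_thresholds(behavior: pd.DataFrame, mode: str = "fixed",
                      per_subject: bool = False):
    """Build the categorization rule.

    ``fixed`` returns the study cut-offs (10.2, 4) regardless of data;
    ``median_split`` returns per-dataset medians (or a dict of per-subject
    rules when ``per_subject``). All-identical values make a median split
    degenerate and raise a DesignError naming the variable.
    """
    if mode == "fixed":
        return QuadrantRule(10.2, 4.0, "fixed")
    if mode != "median_split":
        raise ValidationError(f"unknown categorization mode {mode!r}")
    if len(behavior) < 2:
        raise DesignError("median split needs at least 2 trials")

    def _one(df: pd.DataFrame) -> QuadrantRule:
        for var in ("score", "control"):
            if df[var].nunique() == 1:
                raise DesignError(f"median split degenerate: all {var!r} "
                                  "values identical")
        return QuadrantRule(float(df["score"].median()),
                            float(df["control"].median()), "median_split")

    if per_subject:
        return {s: _one(g) for s, g in behavior.groupby("subject")}
    return _one(behavior)


def assign_quadrant(score: float, control: float,
                    rule: QuadrantRule) -> PerformanceType:
    """One MAP type per trial; boundary closure: optimal iff score ≥
    threshold, automatic iff control ≤ threshold."""
    if not SCORE_RANGE[0] <= score <= SCORE_RANGE[1]:
        raise ValidationError(f"score {score} outside [0, 10.9]")
    if not CONTROL_RANGE[0] <= control <= CONTROL_RANGE[1]:
        raise ValidationError(f"control {control} outside [0, 11]")
    optimal = score >= rule.score_threshold
    automatic = control <= rule.control_threshold
    if optimal:
        return (PerformanceType.TYPE1_OPTIMAL_AUTOMATIC if automatic
                else PerformanceType.TYPE2_OPTIMAL_CONTROLLED)
    return (PerformanceType.TYPE4_SUBOPTIMAL_AUTOMATIC if automatic
            else PerformanceType.TYPE3_SUBOPTIMAL_CONTROLLED)


def categorize(behavior: pd.DataFrame, rule) -> pd.DataFrame:
    """Append a ``ptype`` column; ``rule`` may be a QuadrantRule or a
    per-subject dict from :func:`derive_thresholds`."""
    out = behavior.copy()
    if isinstance(rule, dict):
        out["ptype"] = [int(assign_quadrant(r.score, r.control, rule[r.subject]))
                        for r in out.itertuples()]
    else:
        out["ptype"] = [int(assign_quadrant(s, c, rule))
                        for s, c in zip(out["score"], out["control"])]
    return out


def quadrant_counts(behavior: pd.DataFrame, rule=None) -> pd.Series:
    """Trial counts per performance type (all four types always present)."""
    df = behavior if "ptype" in behavior.columns else categorize(behavior, rule)
    counts = df["ptype"].value_counts().reindex([1, 2, 3, 4], fill_value=0)
    counts.index.name = "ptype"
    return counts.astype(int)
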