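"""Evaluator-based cellulite severity: grades, severity-scale classes and
baseline normalisation.

Two human-rating instruments are supported: the Nürnberger–Müller grade
(integer 0–3, none to dimpling at rest) assigned per photograph by blinded
evaluators, and the composite Cellulite Severity Scale (CSS, 0–15) classed
Mild (≤5), Moderate (≤10) or Severe (>10).  Longitudinal series are
normalised to each participant's pre-treatment value so statistical testing
can run on percent-of-baseline data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GradeRecord",
    "CssRecord",
    "aggregate_grades",
    "classify_css",
    "normalize_to_baseline",
]

log = logging.getLogger(__name__)

THIGHS = ("placebo", "herbal")
WEEKS = (0, 2, 4, 8, 12, 14)


@dataclass(frozen=True)
class GradeRecord:
    """One evaluator's Nürnberger–Müller grade for one thigh at one visit."""

    participant_id: str
    thigh: str
    week: int
    evaluator_id: str
    grade: int

    def __post_init__(self) -> None:
        if self.grade not in (0, 1, 2, 3):
            raise ValueError("grade must be an integer in 0..3")
        if self.thigh not in THIGHS:
            raise ValueError(f"thigh must be one of {THIGHS}")


@dataclass(frozen=True)
class CssRecord:
    """A Cellulite Severity Scale value with its severity class.

    ``item_scores`` optionally carries five 0–3 item ratings whose sum is
    the css value (the usual convention for five-item severity scales); the
    composite itself is otherwise treated as a measured input.
    """

    participant_id: str
    thigh: str
    week: int
    css: float
    css_class: str = ""
    item_scores: tuple | None = None

    def __post_init__(self) -> None:
        expected = classify_css(self.css)
        if self.css_class == "":
            object.__setattr__(self, "css_class", expected)
        elif self.css_class != expected:
            raise ValueError(
                f"css_class {self.css_class!r} inconsistent with css={self.css} "
                f"({expected})"
            )
        if self.item_scores is not None:
            items = tuple(self.item_scores)
            if len(items) != 5 or any(i not in (0, 1, 2, 3) for i in items):
                raise ValueError("item_scores must be five integers in 0..3")
            if sum(items) != self.css:
                raise ValueError("item_scores must sum to css")


def classify_css(css) -> str:
    """Severity class of a CSS value: Mild ≤5 < Moderate ≤10 < Severe ≤15.

    Boundaries are half-open upward so non-integer evaluator means (e.g.
    12.9) classify deterministically; 0 is reported as Mild.
    """
    arr = np.asarray(css, dtype=float)
    if np.any(arr < 0) or np.any(arr > 15):
        raise ValueError("css must lie in [0, 15]")
    classes = np.where(arr <= 5, "Mild", np.where(arr <= 10, "Moderate", "Severe"))
    return classes.item() if arr.ndim == 0 else classes


def _as_frame(records, columns) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        missing = set(columns) - set(records.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        return records
    return pd.DataFrame([vars(r) if not isinstance(r, dict) else r for r in records])


def aggregate_grades(records) -> pd.DataFrame:
    """Mean grade and SEM over evaluators per (participant, thigh, week).

    SEM uses the n−1 denominator and is 0 when a cell has one evaluator.
    Cells absent from the input stay absent — nothing is imputed.
    """
    df = _as_frame(
        records, ["participant_id", "thigh", "week", "evaluator_id", "grade"]
    )
    if df.duplicated(["participant_id", "thigh", "week", "evaluator_id"]).any():
        raise ValueError("duplicate (participant, thigh, week, evaluator) records")
    grouped = df.groupby(["participant_id", "thigh", "week"])["grade"]
    out = grouped.agg(
        mean_grade="mean",
        n_evaluators="count",
        sd=lambda g: g.std(ddof=1) if len(g) > 1 else 0.0,
    ).reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n_evaluators"])
    return out.drop(columns="sd")


def normalize_to_baseline(
    df: pd.DataFrame,
    value_col: str = "value",
    baseline_week: int = 0,
    group_cols=("participant", "thigh"),
) -> pd.DataFrame:
    """Express each participant-thigh series as percent of its baseline.

    The baseline week maps to exactly 100.  Series whose baseline is
    missing or 0 are excluded with a logged warning rather than propagated
    as infinities.
    """
    group_cols = list(group_cols)
    base = df[df["week"] == baseline_week][group_cols + [value_col]].rename(
        columns={value_col: "_baseline"}
    )
    merged = df.merge(base, on=group_cols, how="left")
    bad = merged["_baseline"].isna() | (merged["_baseline"] == 0)
    if bad.any():
        dropped = merged.loc[bad, group_cols].drop_duplicates()
        log.warning(
            "excluding %d series with missing/zero baseline: %s",
            len(dropped),
            dropped.to_dict("records"),
        )
        merged = merged[~bad]
    out = merged.copy()
    out[value_col] = 100.0 * out[value_col] / out["_baseline"]
    return out.drop(columns="_baseline")
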