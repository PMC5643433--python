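"""Questionnaire scoring and midpoint t-tests.

The 17-item questionnaire (items drawn from the Igroup Presence
Questionnaire, the Presence Questionnaire, the System Usability Scale and
the Simulator Sickness Questionnaire; all items on a 1-5 rating scale)
is scored into eight scales as the unweighted mean of each scale's items.
Item 17 asks for the favourite video and belongs to no scale.

Each scale is tested one-sided against the scale midpoint of 2.5:
usability, immersion, presence, realism and involvement are expected above
the midpoint; sickness, oculomotor problems and disorientation below it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScaleDefinition",
    "TTestResult",
    "DEFAULT_SCALES",
    "MIDPOINT",
    "score_scales",
    "midpoint_ttest",
    "questionnaire_report",
]

MIDPOINT = 2.5


@dataclass(frozen=True)
class ScaleDefinition:
    name: str
    items: tuple[int, ...]
    direction: str  # "above" or "below" the midpoint

    def __post_init__(self) -> None:
        if self.direction not in ("above", "below"):
            raise ValueError("direction must be 'above' or 'below'")
        for i in self.items:
            if not 1 <= i <= 17:
                raise ValueError(f"item number {i} outside 1..17")
            if i == 17:
                raise ValueError("item 17 (favourite video) belongs to no scale")


DEFAULT_SCALES: tuple[ScaleDefinition, ...] = (
    ScaleDefinition("usability", (7, 8, 9), "above"),
    ScaleDefinition("sickness", (10, 11, 12, 15), "below"),
    ScaleDefinition("oculomotor_problems", (13, 14), "below"),
    ScaleDefinition("disorientation", (16,), "below"),
    ScaleDefinition("immersion", (1,), "above"),
    ScaleDefinition("presence", (2,), "above"),
    ScaleDefinition("realism", (5,), "above"),
    ScaleDefinition("involvement", (3, 4, 6), "above"),
)


@dataclass(frozen=True)
class TTestResult:
    scale: str
    mean: float
    sd: float
    t: float
    df: int
    p: float
    direction: str
    degenerate: bool = False  # zero spread: t undefined


def score_scales(
    responses: pd.DataFrame,
    definitions: tuple[ScaleDefinition, ...] = DEFAULT_SCALES,
) -> pd.DataFrame:
    """Score item responses into per-participant scale means.

    ``responses`` holds one row per participant with columns ``item_1`` ..
    ``item_17``. Responses outside [1, 5] are rejected naming the item and
    participant; a missing item leaves that participant's scale missing
    without affecting other scales.
    """
    out = pd.DataFrame({"participant_id": responses["participant_id"]})
    item_cols = {i for d in definitions for i in d.items}
    for i in sorted(item_cols):
        col = f"item_{i}"
        if col not in responses.columns:
            raise ValueError(f"responses table lacks column {col!r}")
        vals = responses[col]
        bad = vals.notna() & ((vals < 1) | (vals > 5))
        if bad.any():
            pid = responses.loc[bad, "participant_id"].iloc[0]
            raise ValueError(
                f"response out of the 1-5 scale: item {i}, participant {pid}"
            )
    for d in definitions:
        cols = [f"item_{i}" for i in d.items]
        block = responses[cols].astype(float)
        # scale is missing whenever any of its items is missing
        out[d.name] = block.mean(axis=1).where(block.notna().all(axis=1))
    return out


def midpoint_ttest(
    scores: pd.Series | np.ndarray,
    midpoint: float = MIDPOINT,
    direction: str = "above",
    scale: str = "",
) -> TTestResult:
    """One-sided one-sample t-test of scale scores against the midpoint.

    ``t = (mean - midpoint) / (sd / sqrt(n))`` on ``n - 1`` degrees of
    freedom; the alternative is mean > midpoint (``above``) or mean <
    midpoint (``below``). Zero spread leaves t undefined (flagged
    degenerate).
    """
    if direction not in ("above", "below"):
        raise ValueError("direction must be 'above' or 'below'")
    vals = np.asarray(pd.Series(scores).dropna(), dtype=float)
    n = len(vals)
    if n < 2:
        raise ValueError("need at least 2 scores")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    if sd == 0:
        return TTestResult(scale, mean, sd, np.nan, n - 1, np.nan, direction, degenerate=True)
    alternative = "greater" if direction == "above" else "less"
    res = stats.ttest_1samp(vals, midpoint, alternative=alternative)
    return TTestResult(scale, mean, sd, float(res.statistic), n - 1, float(res.pvalue), direction)


def questionnaire_report(
    scores: pd.DataFrame,
    definitions: tuple[ScaleDefinition, ...] = DEFAULT_SCALES,
    midpoint: float = MIDPOINT,
) -> pd.DataFrame:
    """Midpoint t-tests for every scale, one row per scale (M, SD, t, df, p)."""
    rows = []
    for d in definitions:
        r = midpoint_ttest(scores[d.name], midpoint, d.direction, d.name)
        rows.append({"scale": r.scale, "items": ",".join(map(str, d.items)),
                     "direction": r.direction, "mean": r.mean, "sd": r.sd,
                     "t": r.t, "df": r.df, "p": r.p})
    return pd.DataFrame(rows)
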