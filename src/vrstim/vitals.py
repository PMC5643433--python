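"""Vital-sign aggregation onto the analysis grid.

Raw monitor records (HF, MAP, RF, SpO2) are reduced to two-minute medians
and then approximated to three measurements per video — begin, middle and
end — giving each participant up to nine analysis points (``time_index``
1..9 for three videos), the grid on which the mixed models run.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["SIGNALS", "two_minute_medians", "to_analysis_grid"]

log = logging.getLogger(__name__)

SIGNALS = ("hf", "map", "rf", "spo2")
POSITIONS = ("begin", "middle", "end")


def two_minute_medians(records: pd.DataFrame, interval_s: float = 120.0) -> pd.DataFrame:
    """Median of each signal over contiguous ``interval_s`` bins per participant.

    Bin ``k`` covers ``((k-1)*interval, k*interval]`` and is emitted at the
    bin end time (the median of the preceding two minutes); bins with no
    samples between the participant's first and last occupied bin are
    emitted with missing values.
    """
    if interval_s <= 0:
        raise ValueError("interval_s must be positive")
    out = []
    for pid, grp in records.groupby("participant_id", sort=True):
        t = grp["t_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            raise ValueError(f"timestamps must be sorted per participant (participant {pid})")
        bins = np.maximum(np.ceil(t / interval_s - 1e-9).astype(int), 1)
        agg = grp.assign(_bin=bins).groupby("_bin")[list(SIGNALS)].median()
        full = agg.reindex(range(agg.index.min(), agg.index.max() + 1))
        full.insert(0, "participant_id", pid)
        full.insert(1, "t_s", full.index.to_numpy() * interval_s)
        out.append(full.reset_index(drop=True))
    return pd.concat(out, ignore_index=True)


def to_analysis_grid(
    medians: pd.DataFrame,
    video_schedule: list[tuple[float, float]],
) -> pd.DataFrame:
    """Assign the nearest two-minute median to each video's begin/middle/end.

    For each video ``(start, end)`` the anchor times are the 0%, 50% and
    100% points of the video; the candidate records are those with
    timestamps inside the video span (records on a shared boundary belong
    to the earlier video). Nearness ties break toward the earlier record.
    A video with no available medians yields missing values for all three
    positions.
    """
    rows = []
    for pid, grp in medians.groupby("participant_id", sort=True):
        t = grp["t_s"].to_numpy(dtype=float)
        for v, (start, end) in enumerate(video_schedule, start=1):
            if v == 1:
                in_video = (t >= start) & (t <= end)
            else:
                in_video = (t > start) & (t <= end)
            cand = grp[in_video]
            anchors = (start, (start + end) / 2.0, end)
            if len(cand) == 0:
                log.warning("participant %s video %d has no vital medians", pid, v)
            for rank, (position, anchor) in enumerate(zip(POSITIONS, anchors), start=1):
                row = {
                    "participant_id": pid,
                    "video_index": v,
                    "position": position,
                    "time_index": 3 * (v - 1) + rank,
                }
                if len(cand) == 0:
                    row.update({s: np.nan for s in SIGNALS})
                else:
                    ct = cand["t_s"].to_numpy(dtype=float)
                    dist = np.abs(ct - anchor)
                    nearest = cand.iloc[int(np.argmin(dist))]  # argmin takes the earliest tie
                    row.update({s: nearest[s] for s in SIGNALS})
                rows.append(row)
    return pd.DataFrame(rows)
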