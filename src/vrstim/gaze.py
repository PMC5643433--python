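"""Gaze-event parsing and moving-window oculomotor features.

The processing chain mirrors the study's pre-processing: gaze samples are
resampled to a uniform 60 Hz grid, eye-closure gaps longer than 20 frames
(0.33 s) are removed, fixations are identified with the dispersion-threshold
(I-DT) algorithm (minimum duration 100 ms, maximum dispersion 2 deg), and
four features are extracted with a 60 s sliding window stepped one sample
(1/60 s) at a time: fixation duration [ms/s], number of fixations per
second, mean saccade amplitude [deg] and the fixation/saccade ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FixationEvent",
    "SaccadeEvent",
    "resample_to_60hz",
    "remove_closure_gaps",
    "detect_fixations_idt",
    "sliding_window_features",
    "events_to_frame",
]

_EPS = 1e-9


@dataclass(frozen=True)
class FixationEvent:
    """A period of stable gaze: >= 100 ms within 2 deg dispersion."""

    start: float
    end: float
    cx: float
    cy: float

    @property
    def duration_ms(self) -> float:
        return (self.end - self.start) * 1000.0


@dataclass(frozen=True)
class SaccadeEvent:
    """Inter-fixation gaze shift; amplitude is the centroid-to-centroid distance."""

    start: float
    end: float
    amplitude: float


def events_to_frame(fixations: list[FixationEvent], saccades: list[SaccadeEvent]) -> pd.DataFrame:
    """Tidy events table (type, start_s, end_s, cx, cy, amplitude_deg)."""
    rows = [
        {"type": "fixation", "start_s": f.start, "end_s": f.end, "cx": f.cx, "cy": f.cy,
         "amplitude_deg": np.nan}
        for f in fixations
    ] + [
        {"type": "saccade", "start_s": s.start, "end_s": s.end, "cx": np.nan, "cy": np.nan,
         "amplitude_deg": s.amplitude}
        for s in saccades
    ]
    df = pd.DataFrame(rows, columns=["type", "start_s", "end_s", "cx", "cy", "amplitude_deg"])
    return df.sort_values("start_s", ignore_index=True)


def resample_to_60hz(samples: pd.DataFrame, rate: float = 60.0) -> pd.DataFrame:
    """Resample a gaze trace onto a uniform grid by linear interpolation.

    The grid spans the input time range at ``rate`` Hz. A resampled point is
    valid only when both bracketing input samples are valid.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to resample")
    t = samples["t_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    n = int(math.floor((t[-1] - t[0]) * rate + _EPS)) + 1
    grid = t[0] + np.arange(n) / rate
    x = np.interp(grid, t, samples["x_deg"].to_numpy(dtype=float))
    y = np.interp(grid, t, samples["y_deg"].to_numpy(dtype=float))
    # interpolating the validity indicator gives 1.0 exactly iff both
    # bracketing samples are valid (or the point coincides with a valid one)
    v = np.interp(grid, t, samples["valid"].to_numpy(dtype=float))
    valid = v >= 1.0 - 1e-9
    out = pd.DataFrame({"t_s": grid, "x_deg": x, "y_deg": y, "valid": valid})
    for col in ("video", "target"):
        if col in samples.columns:
            idx = np.clip(np.searchsorted(t, grid + _EPS) - 1, 0, len(t) - 1)
            out[col] = samples[col].to_numpy()[idx]
    return out


def _invalid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs of consecutive invalid samples."""
    runs = []
    n = len(valid)
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def remove_closure_gaps(samples: pd.DataFrame, max_closed_frames: int = 20) -> pd.DataFrame:
    """Delete eye-closure gaps longer than ``max_closed_frames`` samples.

    Runs of strictly more than ``max_closed_frames`` consecutive invalid
    samples are dropped (blink data removed); shorter runs are retained with
    coordinates linearly interpolated through the gap and marked valid.
    """
    valid = samples["valid"].to_numpy(dtype=bool)
    if valid.all():
        return samples.reset_index(drop=True)
    keep = np.ones(len(samples), dtype=bool)
    fill = np.zeros(len(samples), dtype=bool)
    for i, j in _invalid_runs(valid):
        if j - i > max_closed_frames:
            keep[i:j] = False
        else:
            fill[i:j] = True
    out = samples.copy()
    if fill.any():
        t = out["t_s"].to_numpy(dtype=float)
        for col in ("x_deg", "y_deg"):
            vals = out[col].to_numpy(dtype=float)
            out[col] = np.where(fill, np.interp(t, t[valid], vals[valid]), vals)
        out.loc[fill, "valid"] = True
    return out[keep].reset_index(drop=True)


def _idt_segment(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    min_duration_s: float,
    max_dispersion: float,
) -> list[FixationEvent]:
    """Dispersion-threshold identification on one contiguous segment.

    Grows a window while the dispersion (max-min in x plus max-min in y)
    stays within the threshold; a window is a fixation once it also covers
    the minimum duration (inclusive).
    """
    n = len(t)
    fixations: list[FixationEvent] = []
    i = 0
    while i < n:
        # smallest window [i..j] covering the minimum duration
        j = int(np.searchsorted(t, t[i] + min_duration_s - _EPS, side="left"))
        if j >= n:
            break
        xmin = x[i:j + 1].min(); xmax = x[i:j + 1].max()
        ymin = y[i:j + 1].min(); ymax = y[i:j + 1].max()
        if (xmax - xmin) + (ymax - ymin) <= max_dispersion + _EPS:
            while j + 1 < n:
                nx, ny = x[j + 1], y[j + 1]
                d = (max(xmax, nx) - min(xmin, nx)) + (max(ymax, ny) - min(ymin, ny))
                if d > max_dispersion + _EPS:
                    break
                j += 1
                xmin = min(xmin, nx); xmax = max(xmax, nx)
                ymin = min(ymin, ny); ymax = max(ymax, ny)
            fixations.append(
                FixationEvent(start=float(t[i]), end=float(t[j]),
                              cx=float(x[i:j + 1].mean()), cy=float(y[i:j + 1].mean()))
            )
            i = j + 1
        else:
            i += 1
    return fixations


def detect_fixations_idt(
    samples: pd.DataFrame,
    min_duration_ms: float = 100.0,
    max_dispersion_deg: float = 2.0,
    rate: float = 60.0,
) -> tuple[list[FixationEvent], list[SaccadeEvent]]:
    """I-DT fixation detection plus inter-fixation saccade events.

    The trace is split at timestamp discontinuities (deleted closure gaps)
    and fixations are detected per contiguous segment; saccades connect
    consecutive fixations within a segment with amplitude equal to the
    Euclidean distance between their centroids. Returns empty lists for an
    empty input.
    """
    if len(samples) == 0:
        return [], []
    t = samples["t_s"].to_numpy(dtype=float)
    x = samples["x_deg"].to_numpy(dtype=float)
    y = samples["y_deg"].to_numpy(dtype=float)
    min_dur_s = min_duration_ms / 1000.0

    gap = 1.5 / rate
    breaks = np.flatnonzero(np.diff(t) > gap) + 1
    segments = np.split(np.arange(len(t)), breaks)

    fixations: list[FixationEvent] = []
    saccades: list[SaccadeEvent] = []
    for seg in segments:
        if len(seg) < 2:
            continue
        seg_fix = _idt_segment(t[seg], x[seg], y[seg], min_dur_s, max_dispersion_deg)
        for a, b in zip(seg_fix, seg_fix[1:]):
            saccades.append(
                SaccadeEvent(start=a.end, end=b.start,
                             amplitude=float(np.hypot(b.cx - a.cx, b.cy - a.cy)))
            )
        fixations.extend(seg_fix)
    return fixations, saccades


def _interval_cum(starts: np.ndarray, ends: np.ndarray):
    """Piecewise-linear cumulative covered-time function over sorted disjoint intervals."""
    durs = ends - starts
    cum = np.concatenate([[0.0], np.cumsum(durs)])
    xs = np.empty(2 * len(starts))
    ys = np.empty(2 * len(starts))
    xs[0::2] = starts
    xs[1::2] = ends
    ys[0::2] = cum[:-1]
    ys[1::2] = cum[1:]
    return xs, ys


def sliding_window_features(
    fixations: list[FixationEvent],
    saccades: list[SaccadeEvent],
    times: np.ndarray,
    target_flags: np.ndarray,
    window_s: float = 60.0,
    rate: float = 60.0,
    trace_span: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Windowed oculomotor features at each grid time.

    For every time ``t`` in ``times`` the window ``[t - w/2, t + w/2]``
    (truncated at the trace boundaries) is aggregated:

    * ``fix_dur_ms_per_s`` — total fixation time in the window, in ms per
      second of window coverage;
    * ``n_fix_per_s`` — count of fixations overlapping the window per second
      of coverage;
    * ``sacc_amp_deg`` — mean amplitude of the saccades overlapping the
      window (missing when none);
    * ``fix_sacc_ratio`` — total fixation time over total saccade time in
      the window (missing when no saccade time); a zero-length saccade
      interval contributes one sample period.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    times = np.asarray(times, dtype=float)
    target_flags = np.asarray(target_flags)
    if trace_span is None:
        trace_span = (float(times[0]), float(times[-1])) if len(times) else (0.0, 0.0)
    t0, t1 = trace_span
    half = window_s / 2.0
    a = np.maximum(times - half, t0)
    b = np.minimum(times + half, t1)
    coverage = np.maximum(b - a, _EPS)

    n = len(times)
    out = pd.DataFrame(
        {
            "t_s": times,
            "fix_dur_ms_per_s": np.zeros(n),
            "n_fix_per_s": np.zeros(n),
            "sacc_amp_deg": np.full(n, np.nan),
            "fix_sacc_ratio": np.full(n, np.nan),
            "target": target_flags.astype(int),
        }
    )
    if fixations:
        fs = np.array([f.start for f in fixations])
        fe = np.array([f.end for f in fixations])
        xs, ys = _interval_cum(fs, fe)
        fix_time = np.interp(b, xs, ys) - np.interp(a, xs, ys)
        n_fix = np.searchsorted(fs, b, side="left") - np.searchsorted(fe, a, side="right")
        out["fix_dur_ms_per_s"] = fix_time * 1000.0 / coverage
        out["n_fix_per_s"] = n_fix / coverage
    else:
        fix_time = np.zeros(n)
    if saccades:
        ss = np.array([s.start for s in saccades])
        se_raw = np.array([s.end for s in saccades])
        se = np.maximum(se_raw, ss + 1.0 / rate)  # degenerate intervals: one sample period
        amps = np.array([s.amplitude for s in saccades])
        xs, ys = _interval_cum(ss, se)
        sacc_time = np.interp(b, xs, ys) - np.interp(a, xs, ys)
        lo = np.searchsorted(se, a, side="right")
        hi = np.searchsorted(ss, b, side="left")
        count = hi - lo
        amp_cum = np.concatenate([[0.0], np.cumsum(amps)])
        amp_sum = amp_cum[hi] - amp_cum[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            out["sacc_amp_deg"] = np.where(count > 0, amp_sum / np.maximum(count, 1), np.nan)
            out["fix_sacc_ratio"] = np.where(sacc_time > _EPS, fix_time / sacc_time, np.nan)
    return out
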