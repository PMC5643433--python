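"""Synthetic study data with known ground truth.

Generators for the four data streams the analysis pipeline consumes:

* 60 Hz gaze traces built from an alternating fixation/saccade schedule with
  blink gaps and target-present epochs (longer fixations, smaller saccade
  amplitudes while the target is shown);
* grayscale eye-camera frames containing a dark circular pupil, with
  eyelid-closure frames interspersed;
* per-participant vital-sign series (HF, MAP, RF, SpO2) with negative time
  trends, participant random intercepts and slopes, intercept-slope
  correlation and an age x time interaction on MAP;
* questionnaire scale scores on the 1-5 rating metric.

Every generator is driven by :class:`numpy.random.Generator` seeded
explicitly, so identical seeds yield bit-identical output, and each returns
the ground truth used to build the data so that recovery tests can compare
against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "GazeTruthParams",
    "GazeGroundTruth",
    "VitalGroundTruth",
    "generate_gaze_trace",
    "generate_eye_frames",
    "generate_vitals",
    "generate_questionnaire",
    "generate_item_responses",
    "default_target_epochs",
]

# Vital-sign baselines reflect the measured resting values of the study
# population (healthy adults lying on an ICU bed).
DEFAULT_BASELINES = {"hf": 68.7, "map": 86.8, "rf": 21.0, "spo2": 97.0}

VIDEO_POSITIONS = ("begin", "middle", "end")


def default_target_epochs(video_duration: float, epoch_length: float | None = None):
    """Target epochs at the beginning, the middle and the end of a video."""
    if epoch_length is None:
        epoch_length = min(30.0, video_duration / 5.0)  # scaled down for short videos
    mid = video_duration / 2.0
    return [
        (0.0, epoch_length),
        (mid - epoch_length / 2.0, mid + epoch_length / 2.0),
        (video_duration - epoch_length, video_duration),
    ]


@dataclass
class StudyDesign:
    """Shape of the stimulation protocol: videos, epochs, sampling rates."""

    n_participants: int
    n_videos: int = 3
    video_duration: float = 300.0
    target_epochs: list[tuple[float, float]] | None = None
    gaze_rate: float = 60.0
    vital_interval: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_videos", "video_duration", "gaze_rate", "vital_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.target_epochs is None:
            self.target_epochs = default_target_epochs(self.video_duration)
        prev_end = -np.inf
        for start, end in self.target_epochs:
            if not (0.0 <= start < end <= self.video_duration):
                raise ValueError(
                    f"target epoch ({start}, {end}) must lie inside [0, {self.video_duration}]"
                )
            if start < prev_end:
                raise ValueError("target epochs must be disjoint and ordered")
            prev_end = end

    @property
    def total_duration(self) -> float:
        return self.n_videos * self.video_duration

    @property
    def n_time_points(self) -> int:
        """Analysis grid size: three measurements (begin/middle/end) per video."""
        return 3 * self.n_videos


@dataclass
class GazeTruthParams:
    """True fixation-duration and saccade-amplitude distributions.

    Target-present fixations are longer and target-present saccades smaller,
    reproducing the direction of the target effect on oculomotor features.
    Defaults echo the pooled observed statistics (fixation duration around
    170 ms, saccade amplitude around 14 deg during free viewing).
    """

    fix_dur_mean_ms: float = 170.0
    fix_dur_mean_target_ms: float = 280.0
    fix_dur_sd_ms: float = 50.0
    sacc_amp_mean_deg: float = 14.0
    sacc_amp_mean_target_deg: float = 8.0
    sacc_amp_sd_deg: float = 3.0
    jitter_sd_deg: float = 0.3  # within-fixation positional noise, well under 2 deg
    blink_rate_per_min: float = 10.0
    blink_dur_mean_s: float = 0.15
    long_closure_prob: float = 0.05  # fraction of blinks exceeding the 20-frame limit
    long_closure_dur_s: float = 1.0
    field_half_deg: float = 25.0

    def __post_init__(self) -> None:
        for name in ("fix_dur_mean_ms", "fix_dur_mean_target_ms", "sacc_amp_mean_deg",
                     "sacc_amp_mean_target_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fix_dur_mean_target_ms <= self.fix_dur_mean_ms:
            raise ValueError("target-present fixation duration mean must exceed target-absent mean")
        if self.sacc_amp_mean_target_deg >= self.sacc_amp_mean_deg:
            raise ValueError("target-present saccade amplitude mean must be below target-absent mean")


@dataclass
class GazeGroundTruth:
    """True event schedule behind a generated gaze trace."""

    events: pd.DataFrame  # columns: video, kind, start_s, end_s, cx, cy, amplitude_deg
    blink_intervals: list[tuple[float, float]]
    target_flags: np.ndarray  # per-sample 0/1


def _schedule_video(
    rng: np.random.Generator,
    design: StudyDesign,
    params: GazeTruthParams,
    video: int,
    t_offset: float,
) -> list[dict]:
    """Alternate fixations and instantaneous saccades until the video is tiled."""
    events: list[dict] = []
    epochs = design.target_epochs
    dt = 1.0 / design.gaze_rate
    t = 0.0
    pos = rng.uniform(-5.0, 5.0, size=2)
    half = params.field_half_deg
    while t < design.video_duration:
        on_target = any(s <= t < e for s, e in epochs)
        mean = params.fix_dur_mean_target_ms if on_target else params.fix_dur_mean_ms
        # Gamma keeps durations positive with realistic right skew.
        shape = (mean / max(params.fix_dur_sd_ms, 1e-9)) ** 2
        dur = rng.gamma(shape, mean / shape) / 1000.0 if params.fix_dur_sd_ms > 0 else mean / 1000.0
        dur = max(dur, 2 * dt)
        end = min(t + dur, design.video_duration)
        events.append(
            {"video": video, "kind": "fixation", "start_s": t_offset + t,
             "end_s": t_offset + end, "cx": pos[0], "cy": pos[1], "amplitude_deg": np.nan}
        )
        t = end
        if t >= design.video_duration:
            break
        amp_mean = (
            params.sacc_amp_mean_target_deg if any(s <= t < e for s, e in epochs)
            else params.sacc_amp_mean_deg
        )
        amp = abs(rng.normal(amp_mean, params.sacc_amp_sd_deg))
        theta = rng.uniform(0, 2 * np.pi)
        new = pos + amp * np.array([np.cos(theta), np.sin(theta)])
        # reflect back into the visual field
        new = np.clip(new, -2 * half, 2 * half)
        new = np.where(np.abs(new) > half, np.sign(new) * (2 * half - np.abs(new)), new)
        events.append(
            {"video": video, "kind": "saccade", "start_s": t_offset + t,
             "end_s": t_offset + t + dt, "cx": np.nan, "cy": np.nan,
             "amplitude_deg": float(np.hypot(*(new - pos)))}
        )
        pos = new
        t += dt
    return events


def generate_gaze_trace(
    design: StudyDesign,
    params: GazeTruthParams | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, GazeGroundTruth]:
    """Generate one participant's gaze trace across all videos.

    Returns a samples table (``t_s, x_deg, y_deg, valid, video, target``) at
    ``design.gaze_rate`` and the ground truth behind it. Samples inside blink
    intervals are flagged invalid.
    """
    params = params or GazeTruthParams()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    dt = 1.0 / design.gaze_rate

    all_events: list[dict] = []
    for v in range(1, design.n_videos + 1):
        all_events.extend(_schedule_video(rng, design, params, v, (v - 1) * design.video_duration))
    events = pd.DataFrame(all_events)

    n = int(round(design.total_duration * design.gaze_rate))
    t = np.arange(n) * dt
    x = np.empty(n)
    y = np.empty(n)

    fix = events[events["kind"] == "fixation"]
    idx = np.searchsorted(fix["start_s"].to_numpy(), t, side="right") - 1
    idx = np.clip(idx, 0, len(fix) - 1)
    in_fix = t < fix["end_s"].to_numpy()[idx]
    x = fix["cx"].to_numpy()[idx].copy()
    y = fix["cy"].to_numpy()[idx].copy()
    # samples falling in the single-sample inter-fixation interval take the
    # upcoming fixation's centroid (the jump has already happened)
    nxt = np.clip(idx + 1, 0, len(fix) - 1)
    x[~in_fix] = fix["cx"].to_numpy()[nxt][~in_fix]
    y[~in_fix] = fix["cy"].to_numpy()[nxt][~in_fix]
    if params.jitter_sd_deg > 0:
        x = x + rng.normal(0, params.jitter_sd_deg, n)
        y = y + rng.normal(0, params.jitter_sd_deg, n)

    # blink gaps: Poisson onsets, mostly short, occasionally > 20 frames
    blink_intervals: list[tuple[float, float]] = []
    valid = np.ones(n, dtype=bool)
    if params.blink_rate_per_min > 0:
        n_blinks = rng.poisson(params.blink_rate_per_min * design.total_duration / 60.0)
        onsets = np.sort(rng.uniform(0, design.total_duration, n_blinks))
        for onset in onsets:
            if rng.uniform() < params.long_closure_prob:
                dur = params.long_closure_dur_s * rng.uniform(0.8, 1.5)
            else:
                dur = max(rng.exponential(params.blink_dur_mean_s), 2 * dt)
            close = min(onset + dur, design.total_duration)
            if blink_intervals and onset <= blink_intervals[-1][1]:
                blink_intervals[-1] = (blink_intervals[-1][0], max(blink_intervals[-1][1], close))
            else:
                blink_intervals.append((onset, close))
        for s, e in blink_intervals:
            valid[(t >= s) & (t < e)] = False

    video_idx = np.minimum(t // design.video_duration, design.n_videos - 1).astype(int) + 1
    t_in_video = t - (video_idx - 1) * design.video_duration
    target = np.zeros(n, dtype=int)
    for s, e in design.target_epochs:
        target[(t_in_video >= s) & (t_in_video < e)] = 1

    samples = pd.DataFrame(
        {"t_s": t, "x_deg": x, "y_deg": y, "valid": valid, "video": video_idx, "target": target}
    )
    return samples, GazeGroundTruth(events=events, blink_intervals=blink_intervals,
                                    target_flags=target)


def generate_eye_frames(
    n_frames: int,
    pupil_center_px: tuple[float, float],
    pupil_radius_px: float,
    closure_frames: set[int] | None = None,
    image_size_px: tuple[int, int] = (160, 120),
    noise_sd: float = 0.0,
    seed: int = 0,
    background: float = 170.0,
    pupil_intensity: float = 40.0,
    lid_intensity: float = 120.0,
) -> tuple[np.ndarray, dict]:
    """Grayscale eye frames: a dark pupil disc on a brighter background.

    ``closure_frames`` indexes frames rendered as a uniform eyelid texture
    with no disc. Returns a ``(n_frames, h, w)`` uint8 stack and a ground
    truth dict with the true centre, radius and closure set.
    """
    w, h = image_size_px
    cx, cy = pupil_center_px
    r = float(pupil_radius_px)
    if r < 3:
        raise ValueError("pupil_radius_px must be >= 3")
    if not (r <= cx <= w - 1 - r and r <= cy <= h - 1 - r):
        raise ValueError("pupil disc must lie fully inside the frame")
    closure = set() if closure_frames is None else set(closure_frames)
    rng = np.random.default_rng(seed)

    yy, xx = np.mgrid[0:h, 0:w]
    dist = np.hypot(xx - cx, yy - cy)
    # half-pixel anti-aliased edge keeps the Canny ring clean at the boundary
    disc = np.clip(r + 0.5 - dist, 0.0, 1.0)
    open_frame = background + (pupil_intensity - background) * disc
    lid_frame = np.full((h, w), lid_intensity)

    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    for i in range(n_frames):
        base = lid_frame if i in closure else open_frame
        img = base + (rng.normal(0, noise_sd, (h, w)) if noise_sd > 0 else 0.0)
        frames[i] = np.clip(np.round(img), 0, 255).astype(np.uint8)
    truth = {"center_px": (cx, cy), "radius_px": r, "closure_frames": sorted(closure)}
    return frames, truth


@dataclass
class VitalGroundTruth:
    """Fixed and random-effect parameters behind the simulated vital signs.

    The time trend ``beta_time`` is expressed per analysis-grid index (the
    integer 1..9 measurement scale: three per video). ``beta_age_time``
    applies to MAP only; SpO2 has no time trend by default (it remained
    constant in observation), overridable via ``beta_time_per_signal``.
    """

    beta_time: float = -0.8
    beta_age_time: float = -0.01
    random_intercept_sd: float = 8.0
    random_slope_sd: float = 0.4
    intercept_slope_corr: float = -0.4
    residual_sd: float = 2.0
    baseline_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    beta_time_per_signal: dict[str, float] = field(default_factory=lambda: {"spo2": 0.0})

    def __post_init__(self) -> None:
        for name in ("random_intercept_sd", "random_slope_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 <= self.intercept_slope_corr <= 1.0:
            raise ValueError("intercept_slope_corr must lie in [-1, 1]")

    def beta_time_for(self, signal: str) -> float:
        return self.beta_time_per_signal.get(signal, self.beta_time)


def generate_vitals(
    design: StudyDesign,
    truth: VitalGroundTruth,
    ages: np.ndarray | list[float],
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate raw vital-sign records, one per ``vital_interval``.

    Each signal follows ``baseline + b0_i + (beta_time + b1_i
    [+ beta_age_time * age_i]) * u(t) + noise`` where ``u(t)`` is the
    continuous measurement index running 1..(3 * n_videos) across the
    stimulation, ``(b0_i, b1_i)`` are participant random effects with the
    stated SDs and correlation, and the age interaction enters for MAP only.
    Ages are used as supplied (centre them for an interpretable intercept).
    """
    ages = np.asarray(ages, dtype=float)
    if len(ages) != design.n_participants:
        raise ValueError("len(ages) must equal design.n_participants")
    rng = np.random.default_rng(seed)

    k = int(design.total_duration // design.vital_interval)
    t_rec = (np.arange(k) + 1) * design.vital_interval
    n_grid = design.n_time_points
    u = 1.0 + (n_grid - 1) * (t_rec - t_rec[0]) / max(t_rec[-1] - t_rec[0], 1e-12)

    rows = []
    signals = ("hf", "map", "rf", "spo2")
    rho = truth.intercept_slope_corr
    re = {}
    for sig in signals:
        z = rng.standard_normal((design.n_participants, 2))
        b0 = truth.random_intercept_sd * z[:, 0]
        b1 = truth.random_slope_sd * (rho * z[:, 0] + np.sqrt(1.0 - rho ** 2) * z[:, 1])
        re[sig] = np.column_stack([b0, b1])
    for i in range(design.n_participants):
        rec = {"participant_id": i + 1, "t_s": t_rec, "time_index": u, "age": ages[i]}
        for sig in signals:
            b0, b1 = re[sig][i]
            slope = truth.beta_time_for(sig) + b1
            if sig == "map":
                slope = slope + truth.beta_age_time * ages[i]
            vals = truth.baseline_means[sig] + b0 + slope * u
            if truth.residual_sd > 0:
                vals = vals + rng.normal(0, truth.residual_sd, k)
            if sig == "spo2":
                vals = np.clip(vals, 0.0, 100.0)
            rec[sig] = vals
        rows.append(pd.DataFrame(rec))
    return pd.concat(rows, ignore_index=True)


# Questionnaire scale means/SDs as observed in the study population
# (1-5 rating metric): high usability, low sickness-type scores, mid-scale
# immersion/presence.
DEFAULT_SCALE_MEANS = {
    "usability": 4.5, "sickness": 1.16, "oculomotor_problems": 1.35,
    "disorientation": 1.16, "immersion": 3.6, "presence": 3.11,
    "realism": 2.92, "involvement": 3.08,
}
DEFAULT_SCALE_SDS = {
    "usability": 0.6, "sickness": 0.4, "oculomotor_problems": 0.5,
    "disorientation": 0.5, "immersion": 1.2, "presence": 1.1,
    "realism": 1.38, "involvement": 0.8,
}


def generate_questionnaire(
    scale_means: dict[str, float] | None = None,
    scale_sds: dict[str, float] | None = None,
    n: int = 37,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-participant scale scores, normal around the stated means, clipped to [1, 5]."""
    scale_means = DEFAULT_SCALE_MEANS if scale_means is None else scale_means
    scale_sds = DEFAULT_SCALE_SDS if scale_sds is None else scale_sds
    for name, mean in scale_means.items():
        if not 1.0 <= mean <= 5.0:
            raise ValueError(f"scale mean for {name!r} outside the 1-5 rating scale")
        if scale_sds[name] < 0:
            raise ValueError(f"scale sd for {name!r} must be >= 0")
    rng = np.random.default_rng(seed)
    data = {"participant_id": np.arange(1, n + 1)}
    for name, mean in scale_means.items():
        data[name] = np.clip(rng.normal(mean, scale_sds[name], n), 1.0, 5.0)
    return pd.DataFrame(data)


def generate_item_responses(
    scale_means: dict[str, float] | None = None,
    scale_sds: dict[str, float] | None = None,
    n: int = 37,
    seed: int = 0,
) -> pd.DataFrame:
    """Item-level questionnaire table (``item_1`` .. ``item_17``).

    Items of a scale scatter around the participant's latent scale score and
    are rounded to the integer 1-5 response format; item 17 (favourite
    video) is a categorical 1-3 choice outside every scale.
    """
    from .questionnaire import DEFAULT_SCALES  # local import avoids a cycle

    scores = generate_questionnaire(scale_means, scale_sds, n, seed)
    rng = np.random.default_rng(seed + 1)
    out = {"participant_id": scores["participant_id"].to_numpy()}
    for scale in DEFAULT_SCALES:
        latent = scores[scale.name].to_numpy()
        for item in scale.items:
            vals = np.round(latent + rng.normal(0, 0.3, n))
            out[f"item_{item}"] = np.clip(vals, 1, 5).astype(int)
    out["item_17"] = rng.integers(1, 4, n)
    cols = ["participant_id"] + [f"item_{i}" for i in range(1, 18)]
    return pd.DataFrame(out)[cols]
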