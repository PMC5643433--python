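"""End-to-end orchestration: simulate -> detect -> features -> models -> report.

Each stage reads and writes plain CSV/JSON artifacts in the configured
output directory, so stages can also be run independently (see the CLI).
Every run writes a manifest (config hash, seed, package versions) that is
sufficient to reproduce it.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .gaze import detect_fixations_idt, events_to_frame, remove_closure_gaps, \
    resample_to_60hz, sliding_window_features
from .models import add_rating_effects, nakagawa_r2, oculomotor_model_suite, \
    select_vitals_model
from .pupil import detect_frames
from .questionnaire import DEFAULT_SCALES, questionnaire_report, score_scales
from .synthetic import GazeTruthParams, StudyDesign, VitalGroundTruth, \
    generate_eye_frames, generate_gaze_trace, generate_item_responses, generate_vitals
from .vitals import SIGNALS, to_analysis_grid, two_minute_medians

log = logging.getLogger(__name__)


def _design(config: PipelineConfig) -> StudyDesign:
    return StudyDesign(
        n_participants=config.n_participants,
        n_videos=config.n_videos,
        video_duration=config.video_duration_s,
        gaze_rate=config.gaze_rate_hz,
        vital_interval=config.vital_interval_s,
        seed=config.seed,
    )


def simulate_stage(config: PipelineConfig, out: Path) -> dict:
    """Generate gaze traces, vitals and questionnaire responses."""
    design = _design(config)
    rng = np.random.default_rng(config.seed)
    params = GazeTruthParams()

    traces = []
    for pid in range(1, design.n_participants + 1):
        samples, _truth = generate_gaze_trace(design, params, seed=config.seed * 100_003 + pid)
        samples.insert(0, "participant_id", pid)
        traces.append(samples)
    gaze = pd.concat(traces, ignore_index=True)
    gaze.to_csv(out / "gaze_samples.csv", index=False)

    ages = rng.uniform(20, 85, design.n_participants)
    vt = VitalGroundTruth()
    vitals_raw = generate_vitals(design, vt, ages - ages.mean(), seed=config.seed + 1)
    vitals_raw["age_years"] = np.repeat(ages, vitals_raw.groupby("participant_id").size().iloc[0])
    vitals_raw.to_csv(out / "vitals_raw.csv", index=False)

    items = generate_item_responses(n=design.n_participants, seed=config.seed + 2)
    items.to_csv(out / "questionnaire_items.csv", index=False)
    return {"participants": design.n_participants, "gaze_samples": len(gaze),
            "vital_records": len(vitals_raw)}


def pupil_stage(config: PipelineConfig, out: Path) -> dict:
    """Demonstration of the eye-image chain on synthetic frames."""
    rng = np.random.default_rng(config.seed + 3)
    n = config.n_eye_frames
    closure = set(rng.choice(n, size=max(1, n // 4), replace=False).tolist())
    frames, truth = generate_eye_frames(
        n_frames=n, pupil_center_px=(80, 60), pupil_radius_px=30,
        closure_frames=closure, image_size_px=(160, 120),
        noise_sd=config.eye_frame_noise_sd, seed=config.seed + 4,
    )
    detections = detect_frames(frames, config.detection)
    detections["true_closed"] = detections["frame_index"].isin(closure)
    detections.to_csv(out / "pupil_detections.csv", index=False)
    acc = float((detections["closed"] == detections["true_closed"]).mean())
    return {"frames": n, "closure_accuracy": acc}


def events_stage(config: PipelineConfig, out: Path) -> dict:
    """Gaze pre-processing, I-DT event parsing and windowed features."""
    gaze = pd.read_csv(out / "gaze_samples.csv")
    step = max(1, int(round(config.model_step_s * config.gaze_rate_hz)))
    all_events, all_feats = [], []
    for (pid, video), grp in gaze.groupby(["participant_id", "video"], sort=True):
        res = resample_to_60hz(grp, rate=config.gaze_rate_hz)
        cleaned = remove_closure_gaps(res, config.max_closed_frames)
        fix, sacc = detect_fixations_idt(
            cleaned, config.fixation_min_duration_ms,
            config.fixation_max_dispersion_deg, rate=config.gaze_rate_hz,
        )
        ev = events_to_frame(fix, sacc)
        ev.insert(0, "participant_id", pid)
        ev.insert(1, "video", video)
        all_events.append(ev)
        feats = sliding_window_features(
            fix, sacc,
            cleaned["t_s"].to_numpy()[::step],
            cleaned["target"].to_numpy()[::step],
            window_s=config.feature_window_s, rate=config.gaze_rate_hz,
            trace_span=(float(cleaned["t_s"].iloc[0]), float(cleaned["t_s"].iloc[-1])),
        )
        feats.insert(0, "participant_id", pid)
        feats.insert(1, "video_type", video)
        feats["time"] = feats["t_s"] * config.gaze_rate_hz  # sample-index clock
        all_feats.append(feats)
    events = pd.concat(all_events, ignore_index=True)
    feats = pd.concat(all_feats, ignore_index=True)
    events.to_csv(out / "gaze_events.csv", index=False)
    feats.to_csv(out / "oculomotor_features.csv", index=False)
    return {"fixations": int((events["type"] == "fixation").sum()),
            "saccades": int((events["type"] == "saccade").sum()),
            "feature_windows": len(feats)}


def vitals_stage(config: PipelineConfig, out: Path) -> dict:
    raw = pd.read_csv(out / "vitals_raw.csv")
    medians = two_minute_medians(raw, config.vital_interval_s)
    medians.to_csv(out / "vitals_medians.csv", index=False)
    schedule = [
        (v * config.video_duration_s, (v + 1) * config.video_duration_s)
        for v in range(config.n_videos)
    ]
    grid = to_analysis_grid(medians, schedule)
    grid = grid.merge(
        raw.groupby("participant_id", as_index=False)[["age_years"]].first(),
        on="participant_id", how="left",
    )
    grid.to_csv(out / "vitals_grid.csv", index=False)
    return {"analysis_points": len(grid)}


def models_stage(config: PipelineConfig, out: Path) -> dict:
    """The LMEM ladder per vital sign and the eight-model oculomotor suite."""
    grid = pd.read_csv(out / "vitals_grid.csv")
    grid = grid.rename(columns={"time_index": "time", "video_index": "video_type"})
    grid["age"] = grid["age_years"] - grid["age_years"].mean()

    items = pd.read_csv(out / "questionnaire_items.csv")
    ratings = score_scales(items, DEFAULT_SCALES)

    vitals_report: dict = {}
    for signal in SIGNALS:
        fixed = ("time", "video_type", "age_time") if signal == "map" else ("time", "video_type")
        chosen, ladder = select_vitals_model(grid, signal, fixed, config.model_alpha)
        r2 = nakagawa_r2(chosen)
        rating_tests = add_rating_effects(grid, signal, chosen, ratings)
        vitals_report[signal] = {
            "chosen_model": ladder.loc[ladder["selected"], "model"].iloc[0],
            "random_structure": chosen.random_structure,
            "df_method": chosen.df_method,
            "coefficients": chosen.params.to_dict(orient="records"),
            "ladder": ladder.to_dict(orient="records"),
            "r2_marginal": r2.marginal,
            "r2_conditional": r2.conditional,
            "rating_effects": rating_tests.to_dict(orient="records"),
        }
    (out / "vitals_models.json").write_text(json.dumps(vitals_report, indent=2, default=float))

    feats = pd.read_csv(out / "oculomotor_features.csv")
    suite, deltas = oculomotor_model_suite(feats)
    suite.to_csv(out / "oculomotor_models.csv", index=False)
    deltas.to_csv(out / "oculomotor_delta_r2.csv", index=False)
    return {"vital_models": len(vitals_report), "oculomotor_models": len(suite)}


def questionnaire_stage(config: PipelineConfig, out: Path) -> dict:
    items = pd.read_csv(out / "questionnaire_items.csv")
    scores = score_scales(items, DEFAULT_SCALES)
    scores.to_csv(out / "questionnaire_scores.csv", index=False)
    report = questionnaire_report(scores, DEFAULT_SCALES, config.rating_midpoint)
    report.to_csv(out / "questionnaire_tests.csv", index=False)
    return {"scales": len(report),
            "significant": int((report["p"] < config.model_alpha).sum())}


STAGES = (
    ("simulate", simulate_stage),
    ("detect_pupil", pupil_stage),
    ("events", events_stage),
    ("vitals", vitals_stage),
    ("models", models_stage),
    ("questionnaire", questionnaire_stage),
)


def write_manifest(config: PipelineConfig, out: Path) -> None:
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "vrstim": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] | None = None) -> dict:
    """Run the pipeline end to end (or a subset of stages, in order).

    Returns a run report with per-stage timings and record counts; all
    artifacts are written under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_manifest(config, out)
    report: dict = {"stages": {}}
    for name, fn in STAGES:
        if stages is not None and name not in stages:
            continue
        t0 = time.perf_counter()
        log.info("stage %s: starting", name)
        info = fn(config, out)
        elapsed = time.perf_counter() - t0
        log.info("stage %s: done in %.1fs %s", name, elapsed, info)
        report["stages"][name] = {"seconds": round(elapsed, 2), **info}
    (out / "run_report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
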