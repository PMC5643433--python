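import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # idt_oracle helper

from vrstim import (
    GazeTruthParams,
    StudyDesign,
    detect_fixations_idt,
    generate_gaze_trace,
    remove_closure_gaps,
    sliding_window_features,
)


def make_feature_table(
    n_participants: int = 6,
    n_videos: int = 3,
    video_duration: float = 120.0,
    step_samples: int = 60,
    window_s: float = 60.0,
    seed: int = 5,
    params: GazeTruthParams | None = None,
) -> pd.DataFrame:
    """Windowed oculomotor features for a small synthetic cohort."""
    design = StudyDesign(n_participants=n_participants, n_videos=n_videos,
                         video_duration=video_duration, seed=seed)
    rows = []
    for pid in range(1, n_participants + 1):
        samples, _ = generate_gaze_trace(design, params, seed=seed * 1000 + pid)
        for vid, grp in samples.groupby("video"):
            clean = remove_closure_gaps(grp.reset_index(drop=True))
            fix, sacc = detect_fixations_idt(clean)
            feats = sliding_window_features(
                fix, sacc,
                clean["t_s"].to_numpy()[::step_samples],
                clean["target"].to_numpy()[::step_samples],
                window_s=window_s,
            )
            feats.insert(0, "participant_id", pid)
            feats["video_type"] = vid
            feats["time"] = feats["t_s"] * 60.0
            rows.append(feats)
    return pd.concat(rows, ignore_index=True)


def random_gaze_trace(rng: np.random.Generator, n_max: int = 2000) -> pd.DataFrame:
    """A random 60 Hz trace mixing stable clusters and drifts/jumps."""
    n = int(rng.integers(50, n_max + 1))
    t = np.arange(n) / 60.0
    x = np.empty(n)
    y = np.empty(n)
    i = 0
    cx, cy = rng.uniform(-20, 20, 2)
    while i < n:
        kind = rng.uniform()
        run = int(rng.integers(2, 40))
        j = min(i + run, n)
        if kind < 0.5:  # stable cluster
            x[i:j] = cx + rng.normal(0, 0.3, j - i)
            y[i:j] = cy + rng.normal(0, 0.3, j - i)
        elif kind < 0.8:  # drift
            x[i:j] = cx + np.linspace(0, rng.uniform(-8, 8), j - i)
            y[i:j] = cy + np.linspace(0, rng.uniform(-8, 8), j - i)
        else:  # jump to a new locus
            cx, cy = rng.uniform(-20, 20, 2)
            x[i:j] = cx + rng.normal(0, 0.3, j - i)
            y[i:j] = cy + rng.normal(0, 0.3, j - i)
        i = j
    return pd.DataFrame({"t_s": t, "x_deg": x, "y_deg": y, "valid": True})


@pytest.fixture(scope="session")
def feature_table() -> pd.DataFrame:
    return make_feature_table()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
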