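"""Pipeline configuration.

All analysis constants live here: the 60 Hz gaze rate, the 20-frame
eye-closure limit, the 100 ms / 2 deg fixation criterion, the 60 s feature
window, the 120 s vital-sign aggregation interval and the questionnaire
midpoint of 2.5 on the 1-5 rating scale. A config round-trips losslessly
through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class DetectionConfig:
    """Parameters of the pupil-detection image chain.

    The Gaussian sigma (0.5) and the 8x8 median filter match the
    pre-processing chain of the eye tracker; Canny thresholds default to
    ``None`` which selects them per frame from an Otsu threshold on the
    gradient magnitude. The accumulator threshold is the fraction of a
    perfect circle's (normalized) Hough score below which no pupil is
    reported.
    """

    gaussian_sigma: float = 0.5
    median_size: int = 8
    canny_sigma: float = 1.0
    canny_low: float | None = None
    canny_high: float | None = None
    min_edge_gradient: float = 5.0
    min_object_px: int = 50
    radius_min_px: int = 10
    radius_max_px: int = 80
    accumulator_threshold: float = 0.3

    def __post_init__(self) -> None:
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be positive")
        if self.median_size < 1:
            raise ValueError("median_size must be >= 1")
        if not (0 < self.radius_min_px < self.radius_max_px):
            raise ValueError("radius range must be positive and ordered")
        if self.canny_low is not None and self.canny_high is not None:
            if not self.canny_low < self.canny_high:
                raise ValueError("canny_low must be < canny_high")


@dataclass
class PipelineConfig:
    """End-to-end run configuration with the study's analysis constants."""

    # study design
    n_participants: int = 37
    n_videos: int = 3
    video_duration_s: float = 300.0
    seed: int = 0

    # gaze processing
    gaze_rate_hz: float = 60.0
    max_closed_frames: int = 20
    fixation_min_duration_ms: float = 100.0
    fixation_max_dispersion_deg: float = 2.0
    feature_window_s: float = 60.0

    # vitals
    vital_interval_s: float = 120.0

    # modelling
    model_alpha: float = 0.05
    model_step_s: float = 1.0  # thinning of feature windows fed to the LMEMs

    # questionnaire
    rating_midpoint: float = 2.5

    # pupil-detection demo stage
    n_eye_frames: int = 60
    eye_frame_noise_sd: float = 5.0

    # paths
    output_dir: str = "vrstim_output"

    detection: DetectionConfig = field(default_factory=DetectionConfig)

    def __post_init__(self) -> None:
        positives = {
            "n_participants": self.n_participants,
            "n_videos": self.n_videos,
            "video_duration_s": self.video_duration_s,
            "gaze_rate_hz": self.gaze_rate_hz,
            "max_closed_frames": self.max_closed_frames,
            "fixation_min_duration_ms": self.fixation_min_duration_ms,
            "fixation_max_dispersion_deg": self.fixation_max_dispersion_deg,
            "feature_window_s": self.feature_window_s,
            "vital_interval_s": self.vital_interval_s,
            "model_alpha": self.model_alpha,
            "rating_midpoint": self.rating_midpoint,
        }
        for name, value in positives.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value!r}")
        if isinstance(self.detection, dict):
            self.detection = DetectionConfig(**self.detection)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data or {})

    def config_hash(self) -> str:
        """Stable hash identifying this configuration (for run manifests)."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
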