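"""Pupil detection and eyes-open/eyes-closed classification.

The chain applied to each grayscale eye-camera frame, in order:

1. noise cancelling — Gaussian filter (sigma = 0.5) then an 8 x 8 median
   filter;
2. Canny edge detection, yielding a binary edge image;
3. morphological clean-up — connected components of fewer than 50 pixels
   are removed (8-connectivity);
4. circular Hough transform over a plausible pupil-radius range; the
   highest-scoring circle is the pupil.

A frame is classified eyes-closed when no circle reaches the detection
threshold (a fraction of the normalized score of a perfect circle).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage import feature, filters, morphology, transform

from .config import DetectionConfig

__all__ = [
    "PupilDetection",
    "denoise",
    "edge_map",
    "remove_small_objects",
    "detect_pupil",
    "classify_closure",
    "detect_frames",
    "load_frame_dir",
    "save_frame_dir",
]


def load_frame_dir(path: str | Path, pattern: str = "*.png") -> np.ndarray:
    """Load a directory of grayscale frame images into an (n, h, w) stack.

    Frames are read in lexicographic filename order and converted to 8-bit
    grayscale; PNG and TIFF are the expected formats.
    """
    files = sorted(Path(path).glob(pattern))
    if not files:
        raise ValueError(f"no frames matching {pattern!r} in {path}")
    frames = [np.asarray(Image.open(f).convert("L")) for f in files]
    return np.stack(frames)


def save_frame_dir(frames: np.ndarray, path: str | Path, prefix: str = "frame") -> list[Path]:
    """Write an (n, h, w) uint8 stack as numbered grayscale PNGs."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(len(frames))))
    paths = []
    for i, frame in enumerate(frames):
        p = out / f"{prefix}_{i:0{width}d}.png"
        Image.fromarray(np.asarray(frame, dtype=np.uint8), mode="L").save(p)
        paths.append(p)
    return paths


@dataclass(frozen=True)
class PupilDetection:
    """Best circle found by the Hough transform, if any."""

    found: bool
    cx: float = np.nan
    cy: float = np.nan
    radius: float = np.nan
    score: float = 0.0


def _check_frame(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("frame must be a non-empty 2-D grayscale image")
    return frame


def denoise(frame: np.ndarray, gaussian_sigma: float = 0.5, median_size: int = 8) -> np.ndarray:
    """Gaussian smoothing followed by square median filtering.

    Output has the same dtype and dimensions as the input; constant frames
    pass through unchanged.
    """
    frame = _check_frame(frame)
    smoothed = ndimage.gaussian_filter(frame.astype(float), sigma=gaussian_sigma)
    med = ndimage.median_filter(smoothed, size=median_size)
    if np.issubdtype(frame.dtype, np.integer):
        return np.clip(np.round(med), 0, 255).astype(frame.dtype)
    return med


def edge_map(
    frame: np.ndarray,
    canny_low: float | None = None,
    canny_high: float | None = None,
    sigma: float = 1.0,
    min_edge_gradient: float = 5.0,
) -> np.ndarray:
    """Canny edge detection -> binary edge image.

    When thresholds are not given they are derived per frame from an Otsu
    threshold on the Sobel gradient magnitude (high = Otsu, low = high / 2),
    which adapts to contrast without per-camera tuning. A frame whose Otsu
    gradient threshold falls below ``min_edge_gradient`` (intensity units
    per pixel) has no real structure — flat or noise-only, e.g. a closed
    eyelid — and yields an empty edge map rather than noise contours.
    """
    frame = _check_frame(frame).astype(float)
    if canny_low is not None and canny_high is not None and not canny_low < canny_high:
        raise ValueError("canny_low must be < canny_high")
    if canny_low is None or canny_high is None:
        grad = filters.sobel(frame)
        if grad.max() <= 0:
            return np.zeros(frame.shape, dtype=bool)
        high = filters.threshold_otsu(grad)
        if high < min_edge_gradient:
            return np.zeros(frame.shape, dtype=bool)
        low = high / 2.0
    else:
        low, high = canny_low, canny_high
    return feature.canny(frame, sigma=sigma, low_threshold=low, high_threshold=high)


def remove_small_objects(binary: np.ndarray, min_pixels: int = 50) -> np.ndarray:
    """Drop connected components with fewer than ``min_pixels`` pixels.

    Components of exactly ``min_pixels`` are retained ("fewer than" is
    strict); 8-connectivity.
    """
    binary = np.asarray(binary, dtype=bool)
    # max_size removes components <= its value, so strictly-below-min_pixels
    return morphology.remove_small_objects(binary, max_size=min_pixels - 1, connectivity=2)


def detect_pupil(
    binary: np.ndarray,
    radius_range_px: tuple[int, int] = (10, 80),
    accumulator_threshold: float = 0.3,
) -> PupilDetection:
    """Circular Hough transform restricted to a radius range.

    The normalized accumulator scores a perfect circle near 1.0; the best
    peak below ``accumulator_threshold`` is reported as not found.
    """
    rmin, rmax = radius_range_px
    if not (0 < rmin < rmax):
        raise ValueError("radius range must be positive and ordered")
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        return PupilDetection(found=False)

    def _best(radii: np.ndarray):
        acc = transform.hough_circle(binary, radii)
        return transform.hough_circle_peaks(acc, radii, total_num_peaks=1)

    # coarse sweep over the range, then refine around the best radius
    step = max(1, (rmax - rmin) // 24)
    accums, cxs, cys, rads = _best(np.arange(rmin, rmax + 1, step))
    if len(accums) and step > 1:
        r0 = int(rads[0])
        fine = np.arange(max(rmin, r0 - step), min(rmax, r0 + step) + 1)
        accums, cxs, cys, rads = _best(fine)
    if len(accums) == 0 or accums[0] < accumulator_threshold:
        score = float(accums[0]) if len(accums) else 0.0
        return PupilDetection(found=False, score=score)
    return PupilDetection(found=True, cx=float(cxs[0]), cy=float(cys[0]),
                          radius=float(rads[0]), score=float(accums[0]))


def classify_closure(frame: np.ndarray, config: DetectionConfig | None = None) -> bool:
    """True when the frame shows a closed eye (no pupil found by the full chain)."""
    return not _detect_frame(frame, config or DetectionConfig()).found


def _detect_frame(frame: np.ndarray, config: DetectionConfig) -> PupilDetection:
    den = denoise(frame, config.gaussian_sigma, config.median_size)
    edges = edge_map(den, config.canny_low, config.canny_high, sigma=config.canny_sigma,
                     min_edge_gradient=config.min_edge_gradient)
    cleaned = remove_small_objects(edges, config.min_object_px)
    return detect_pupil(cleaned, (config.radius_min_px, config.radius_max_px),
                        config.accumulator_threshold)


def detect_frames(frames: np.ndarray, config: DetectionConfig | None = None) -> pd.DataFrame:
    """Run the full chain on a frame stack.

    Returns one row per frame: ``frame_index, closed, cx, cy, r, score``.
    """
    config = config or DetectionConfig()
    rows = []
    for i, frame in enumerate(frames):
        det = _detect_frame(frame, config)
        rows.append({"frame_index": i, "closed": not det.found, "cx": det.cx,
                     "cy": det.cy, "r": det.radius, "score": det.score})
    return pd.DataFrame(rows)
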