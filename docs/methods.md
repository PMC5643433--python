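# Methods

This note documents the models and procedures the package implements, the
choices made where the published analysis description leaves details open,
and what the synthetic-data generators do and do not emulate.

## Eye-image processing

Each grayscale eye-camera frame passes through, in order: a Gaussian
filter (σ = 0.5 px), an 8×8 median filter, Canny edge detection, removal
of connected edge components with fewer than 50 pixels (strictly fewer; a
50-pixel component survives), and a circular Hough transform restricted to
a plausible pupil-radius range. The highest-scoring circle is the pupil; a
frame whose best normalized accumulator score falls below 0.3 (a perfect
circle scores ≈ 1) is classified eyes-closed.

Open choices and how they were fixed:

* **Canny thresholds** are not part of the published chain. By default they
  are derived per frame: the high threshold is the Otsu threshold of the
  Sobel gradient magnitude, the low threshold half of it. A frame whose
  Otsu gradient threshold is below 5 intensity units/px is treated as
  structure-free (flat or noise only — a closed lid) and yields an empty
  edge map; without this floor, Otsu happily bisects pure sensor noise and
  produces spurious contours. Both thresholds are config-overridable.
* **Connectivity** for the 50-pixel rule is 8-connectivity, the usual
  choice for thin edge maps.
* **Radius range** defaults to 10–80 px (plausible pupil sizes for a
  VGA-class eye image); the Hough search sweeps the range coarsely and
  refines around the best radius, keeping the radius error within ~1 px.
* **Closure criterion**: eyes-closed ⇔ no circle above the accumulator
  threshold. The original analysis states only that closed-eye frames were
  excluded; the concrete threshold rule is this package's decision and is
  exposed in `DetectionConfig`.

## Gaze events and windowed features

Gaze samples (degrees of visual angle) are linearly resampled onto a
uniform 60 Hz grid spanning the recording; a resampled point is valid only
if both bracketing input samples are valid. Runs of more than 20
consecutive invalid samples (> 0.33 s — real eye closure rather than a
blink) are deleted; runs of up to 20 samples are retained with coordinates
interpolated through the gap.

Fixations are detected with the dispersion-threshold algorithm (I-DT):
a window grows while its dispersion, `(max x − min x) + (max y − min y)`,
stays within 2°, and is emitted as a fixation when it also spans at least
100 ms (inclusive: a 100 ms stable cluster is a fixation, 99 ms is not).
The trace is split at timestamp discontinuities left by gap deletion;
windows never bridge a deleted gap. Consecutive fixations within a
contiguous segment are joined by a saccade event whose amplitude is the
Euclidean distance between the fixation centroids — robust to
intra-saccade noise, and consistent with deriving saccade metrics from the
fixation sequence. The implementation is cross-checked in the test suite
against an independent brute-force window-growing oracle on random traces.

Features use a 60 s window (±30 s) centred on each sample of the 60 Hz
grid:

* fixation duration: total fixation time in the window, normalized to
  ms per second of window coverage;
* number of fixations: count of fixations overlapping the window per
  second of coverage;
* saccade amplitude: mean amplitude of saccades overlapping the window
  (missing when none);
* fixation/saccade ratio: total fixation time divided by total saccade
  time in the window. The published description calls this "the ratio
  between information processing and search activity" without a formula;
  the duration ratio implemented here is the standard reading. A
  zero-length inter-fixation interval contributes one sample period
  (1/60 s) of saccade time so the ratio stays finite; a window with no
  saccade time yields a missing ratio.

At the trace edges windows are truncated and normalized by the actually
covered duration rather than discarding 30 s at each end; whether the
original analysis truncated or discarded is unstated, and truncation
preserves data. Window aggregation is computed with interval prefix sums,
so the full 60 Hz step is cheap; for modelling, windows are thinned to one
per second by default (`model_step_s`) since neighbouring windows overlap
in 59 of 60 seconds anyway.

## Vital signs

Raw monitor records are reduced to medians over contiguous 120 s bins per
participant (the median of the preceding two minutes, emitted at the bin
end; empty interior bins emit missing values). Each video then receives
three analysis points — begin, middle, end — by assigning the median
record nearest to the video's 0%, 50% and 100% time points, ties broken
toward the earlier record; records are never assigned across video
boundaries. Whether the original aggregation used nearest, mean or
interpolated values is unstated; nearest assignment is reproducible and
monotone. The resulting `time_index` runs 1–9 across the three videos and
is the time covariate of the vitals models.

## Mixed models

All models are Gaussian linear mixed-effects models fitted by maximum
likelihood (not REML), so that likelihood-ratio tests across nested random
structures are valid. The vitals ladder is:

1. model 1 — fixed time + video type, random participant intercept;
2. model 2 — plus a random slope of time per participant, with the
   intercept–slope covariance constrained to zero;
3. model 3 — plus the intercept–slope correlation (free covariance).

Each extension is retained when its likelihood-ratio test against the
current model is significant at α = 0.05. The χ² reference with 1 df is
the naive one; for variance components the true null distribution is a
boundary mixture, making the test conservative — a documented caveat, kept
because the published analysis states plain likelihood-ratio tests. For
MAP the fixed effects include the age×time interaction (ages are centred
before fitting). Questionnaire scales are then added one at a time to the
chosen model and their coefficient p-values Holm-adjusted across the eight
scales.

Fixed-effect p-values are conditional t-tests with **residual degrees of
freedom** (`n_obs − rank(X)`); the published tables report t(df) without
naming the df method, so the method used here is recorded in the fit
metadata (`df_method="residual"`). Satterthwaite-style corrections matter
little at the sample sizes involved.

For the oculomotor features the criterion is effect size rather than
p-values (the windowed sample is enormous, inflating significance): per
feature, eight models with a participant random intercept — a zero model
(intercept only), one model per predictor (time, target, video type), the
full model, and the three leave-one-out models. Each fit is summarised by
Nakagawa's marginal and conditional R²:

* marginal = var(Xβ̂) / (var(Xβ̂) + random variance + residual variance),
* conditional = (var(Xβ̂) + random variance) / same denominator,

where the random variance is the random-intercept variance, generalized
for slope models to the average of `zᵢ' Σ̂ zᵢ` over observations. The
zero model's marginal R² is exactly zero by construction. A predictor's
contribution is the drop in marginal R² when it is removed from the full
model.

Numerical notes: the optimizer falls back across lbfgs/bfgs/cg (and
powell for unconstrained fits — powell does not honour the constrained
covariance pattern), accepting the first converged fit and rejecting
spurious boundary optima with non-finite likelihood; a fit whose variance
component collapses to zero is flagged singular but returned; constant
covariates (e.g. a single video) are dropped with a warning rather than
producing a rank-deficient design.

## Questionnaire

Scale scores are unweighted means of their items (items on the integer 1–5
response format): usability 7–9; sickness 10–12, 15; oculomotor problems
13–14; disorientation 16; immersion 1; presence 2; realism 5; involvement
3–4, 6. Item 17 (favourite video) belongs to no scale. Each scale is
tested one-sided against the midpoint 2.5 — above for
usability/immersion/presence/realism/involvement, below for
sickness/oculomotor problems/disorientation, matching the direction of the
published means. A zero-spread score vector leaves t undefined and is
flagged rather than guessed.

Recomputing t from the published scale means/SDs at n = 37 reproduces the
published t(36) values within summary rounding for usability (20.28 vs
20.44), oculomotor problems (−13.99 vs −14.03) and disorientation (−16.30
vs −16.25). The published sickness statistic (−18.10) is **not**
consistent with its published mean/SD under the one-sample formula (which
gives −20.38); the package reports the formula value and this discrepancy
is documented here rather than reconciled by guessing which summary number
is in error.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the pipeline assumes,
with the study's design constants as defaults: 3 videos × 300 s, 60 Hz
gaze, target epochs at the beginning/middle/end of each video (30 s each —
the published description gives the placement but not the duration),
120 s vital records, 37 participants aged 20–85.

* **Gaze**: alternating fixations (Gamma-distributed durations, default
  mean 170 ms matching the observed pooled fixation duration; 280 ms
  during target epochs) and instantaneous single-sample saccades (normal
  amplitudes, mean 14° free-viewing vs 8° on target — the direction of the
  observed target effects). Within-fixation jitter is isotropic Gaussian
  with SD 0.3°, well inside the 2° dispersion criterion. Blinks arrive as
  a Poisson process (10/min), mostly ~150 ms with a 5% fraction of long
  closures (~1 s) that exercise the gap-removal rule.
* **Eye frames**: a dark anti-aliased disc on a brighter background with
  additive Gaussian noise; closure frames are a uniform lid texture. No
  iris/eyelash texture, glints or perspective — deliberately only what the
  detection chain needs.
* **Vitals**: per-signal linear trends on a continuous measurement-index
  scale spanning 1–9 across the stimulation (so nearest-grid aggregation
  leaves the slope unbiased), participant random intercepts and slopes
  with configurable SDs and correlation, an age×time interaction for MAP
  only, and no time trend for SpO2 by default (it remained constant in
  observation). Baselines are the observed resting means (HF 68.7 bpm,
  MAP 86.8 mmHg, RF 21 breaths/min, SpO2 97%). The within-participant
  noise SD (default 2.0 signal units) is a config default, not an
  observed quantity — the magnitude of within-participant vital noise was
  not reported.
* **Questionnaire**: normal scale scores around the published means/SDs,
  clipped to [1, 5]; item-level responses scatter around the latent scale
  score and round to integers.

Passing recovery tests on these generators shows that the pipeline's
implementation is correct under its own assumptions. It does **not** show
robustness to features of real recordings the generators omit: smooth
pursuit on moving scene content, tracker drift and calibration error,
partial eyelid occlusion, measurement artifacts in the vital streams, or
within-window autocorrelation of the oculomotor features (the windowed
samples overlap heavily; like the original analysis, the models assume
independent residuals, which is why effect sizes rather than p-values are
the primary criterion there).

## Problem sizes used in tests and the acceptance script

Recovery checks run at sizes chosen to make the Monte-Carlo error small
relative to the tolerance being asserted: 100 random traces (≤ 2000
samples) for the I-DT oracle; 200 eye frames across noise SDs 0–10 for
pupil recovery; 50 replicates of 50 participants for mixed-model recovery;
200 groups × 50 observations for the constructed Nakagawa partition; and
8 participants × 3 × 300 s videos for the effect-size ordering of the
oculomotor suite.
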