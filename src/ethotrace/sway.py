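"""Stereotypic-sway detection from keypoint displacement.

Sway — rhythmic side-to-side motion of head and trunk — is hard to
localize to an image zone, but it leaves a clear signature in the
distance travelled by the trunk-root keypoint: during a sway bout the
cumulative Euclidean displacement climbs steeply.  This module computes
per-frame step displacements between consecutive valid samples, their
cumulative sum (the trace one plots against manually scored sway), and
segments *bouts* as sustained intervals where the windowed mean
displacement rate exceeds a threshold.

Invalid samples (unlabeled or below the p-cutoff) contribute zero
displacement: charging the jump across a tracking gap would fabricate
motion that never happened.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .io import KeypointTrack

__all__ = [
    "SwayTrace",
    "step_displacements",
    "cumulative_displacement",
    "detect_sway_bouts",
    "sway_trace",
]

#: Sinusoid x(t) = A sin(2*pi*t/T) travels 4A per period, i.e. a mean
#: lateral speed of 4A/T px/s — handy for choosing rate thresholds.
def sinusoid_mean_rate(amplitude_px: float, period_s: float) -> float:
    return 4.0 * amplitude_px / period_s


@dataclass
class SwayTrace:
    """Displacement trace of one body part plus detected sway bouts."""

    bodypart: str
    steps: np.ndarray          # px per frame, >= 0
    cumulative: np.ndarray     # running sum, nondecreasing
    bouts: list[tuple[int, int]]  # (start_s, end_s) half-open, seconds
    fps: float = 25.0


def step_displacements(track: KeypointTrack, bodypart: str,
                       p_cutoff: float | None = None) -> np.ndarray:
    """Per-frame Euclidean step of one body part, zero across gaps.

    ``steps[t]`` is the distance from frame ``t-1`` to frame ``t`` when
    both samples are valid, else 0; ``steps[0]`` is 0.  Validity uses
    the p-cutoff if given (missing samples are always invalid).
    """
    j = track.part_index(bodypart)
    x = track.x[:, j]
    y = track.y[:, j]
    valid = track.valid_mask(p_cutoff)[:, j]
    n = track.n_frames
    steps = np.zeros(n)
    if n < 2:
        return steps
    ok = valid[1:] & valid[:-1]
    dx = np.where(ok, np.diff(x), 0.0)
    dy = np.where(ok, np.diff(y), 0.0)
    steps[1:] = np.hypot(dx, dy)
    return steps


def cumulative_displacement(steps: np.ndarray) -> np.ndarray:
    """Running sum of a nonnegative step series."""
    steps = np.asarray(steps, dtype=float)
    if (steps < 0).any():
        raise ValueError("step displacements must be >= 0")
    return np.cumsum(steps)


def detect_sway_bouts(
    steps: np.ndarray,
    fps: float,
    rate_threshold: float,
    window_s: float = 10.0,
    min_duration_s: float = 5.0,
    merge_gap_s: float = 2.0,
) -> list[tuple[int, int]]:
    """Segment sustained high-displacement intervals as sway bouts.

    A second is *active* when the centered moving average (window
    ``window_s``) of the per-second displacement rate is at or above
    ``rate_threshold`` px/s.  Active runs separated by gaps of at most
    ``merge_gap_s`` seconds are merged, and merged runs shorter than
    ``min_duration_s`` (default 5 s, the minimum for sway to count as a
    bout) are discarded.  Returns half-open (start_s, end_s) intervals.
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    steps = np.asarray(steps, dtype=float)
    n_frames = steps.shape[0]
    if n_frames == 0:
        return []
    n_seconds = int(np.ceil(n_frames / fps))
    sec_idx = (np.arange(n_frames) / fps).astype(np.int64)
    per_second = np.zeros(n_seconds)
    np.add.at(per_second, sec_idx, steps)  # px per second

    w = max(1, int(round(window_s)))
    rate = uniform_filter1d(per_second, size=w, mode="nearest")
    active = rate >= rate_threshold

    runs = _runs(active)
    merged: list[list[int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] <= merge_gap_s:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged if e - s >= min_duration_s]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs where mask is True."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[0::2].tolist(), edges[1::2].tolist()))


def sway_trace(
    track: KeypointTrack,
    bodypart: str = "trunk_root",
    p_cutoff: float | None = None,
    rate_threshold: float = 20.0,
    window_s: float = 10.0,
    min_duration_s: float = 5.0,
    merge_gap_s: float = 2.0,
) -> SwayTrace:
    """Full sway analysis of one body part: steps, cumulative, bouts."""
    steps = step_displacements(track, bodypart, p_cutoff)
    return SwayTrace(
        bodypart=bodypart,
        steps=steps,
        cumulative=cumulative_displacement(steps),
        bouts=detect_sway_bouts(
            steps, track.fps, rate_threshold, window_s, min_duration_s, merge_gap_s
        ),
        fps=track.fps,
    )
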