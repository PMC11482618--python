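"""Synthetic-night generator with known ground truth.

Emulates one 7-hour night (22:00–05:00) of single-elephant CCTV analysis
at 25 FPS: a behavior script (alternating-renewal bout sequence), the
pose track a keypoint model would produce for it (zone-dependent
positions plus jitter, dropout and low-likelihood samples), and the
per-frame detection stream an object-detection model would produce
(label confusion and missed frames).  Because the script is known
exactly, every downstream stage — zone classification, second
aggregation, sway detection, agreement statistics — can be checked
against ground truth.

Stereotypic sway is rendered as a sinusoidal side-to-side oscillation of
the head and trunk-root keypoints, ``x(t) = x0 + A sin(2*pi*t/T)``,
while the animal otherwise stays in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import OUT_OF_VIEW, EthogramConfig
from .io import BehaviorSequence, DetectionStream, KeypointTrack

__all__ = [
    "SimulationScript",
    "NoiseModel",
    "SwayKinematics",
    "DEFAULT_MEAN_BOUT_S",
    "default_noise",
    "default_confusion",
    "random_script",
    "rasterize_script",
    "simulate_night",
]

#: Seconds in a 7-h observation night (22:00 to 05:00).
NIGHT_S = 25_200

#: Mean bout lengths (s) per behavior for the default night script.  With
#: uniform behavior switching, long-run time shares are proportional to
#: these means: ~36% standing, ~38% lying, ~16% foraging, ~8% hay-net,
#: ~2% drinking — the ballpark of captive-elephant night budgets, where
#: recumbent rest occupies roughly a third of the night.
DEFAULT_MEAN_BOUT_S: dict[str, float] = {
    "Standing": 1150.0,
    "Lying down": 1200.0,
    "Foraging": 500.0,
    "Hay-net": 260.0,
    "Drinking": 70.0,
}


@dataclass(frozen=True)
class SimulationScript:
    """Ordered, non-overlapping behavior bouts covering (part of) a night.

    Seconds not covered by any bout rasterize to the config default
    behavior (the animal is present, just unremarkable).
    """

    bouts: tuple[tuple[str, int, int], ...]  # (behavior, start_s, duration_s)
    total_duration_s: int = NIGHT_S
    seed: int | None = None

    def __post_init__(self) -> None:
        prev_end = 0
        for name, start, dur in self.bouts:
            if dur <= 0:
                raise ValueError(f"bout {name!r} at {start}s has duration {dur}")
            if start < prev_end:
                raise ValueError(f"bout {name!r} at {start}s overlaps previous bout")
            prev_end = start + dur
        if prev_end > self.total_duration_s:
            raise ValueError("script extends past total_duration_s")

    def bouts_of(self, behavior: str) -> list[tuple[int, int]]:
        """(start_s, end_s) half-open intervals of one behavior."""
        return [(s, s + d) for b, s, d in self.bouts if b == behavior]


@dataclass(frozen=True)
class SwayKinematics:
    """Sinusoidal sway parameters: lateral amplitude (px) and period (s)."""

    amplitude_px: float = 40.0
    period_s: float = 4.0


@dataclass(frozen=True)
class NoiseModel:
    """Failure modes of the two model families.

    coord_sd:
        Gaussian keypoint jitter, pixels (pose model localization error).
    dropout_p:
        Probability a (frame, bodypart) sample is unlabeled entirely.
    low_conf_p:
        Probability a labeled sample draws a likelihood below the
        p-cutoff (and is therefore discarded by conditioning).
    det_miss_p:
        Probability a frame is unlabeled in the detection stream.
    det_confuse:
        Row-stochastic label-confusion matrix for the detection stream,
        indexed true-behavior x emitted-behavior.
    """

    coord_sd: float = 1.0
    dropout_p: float = 0.05
    low_conf_p: float = 0.05
    det_miss_p: float = 0.10
    det_confuse: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for name in ("dropout_p", "low_conf_p", "det_miss_p"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.coord_sd < 0:
            raise ValueError("coord_sd must be >= 0")
        if self.det_confuse is not None:
            C = self.det_confuse
            if not np.allclose(C.to_numpy().sum(axis=1), 1.0):
                raise ValueError("det_confuse rows must sum to 1")
            if (C.to_numpy() < 0).any():
                raise ValueError("det_confuse entries must be >= 0")


def noiseless() -> NoiseModel:
    """A NoiseModel with every corruption switched off."""
    return NoiseModel(coord_sd=0.0, dropout_p=0.0, low_conf_p=0.0,
                      det_miss_p=0.0, det_confuse=None)


def default_confusion(labels: Sequence[str]) -> pd.DataFrame:
    """Plausible detection confusion for the elephant night ethogram.

    Mostly diagonal, with the documented failure modes of box-based
    detection: drinking read as standing, hay-net reaching read as
    foraging.  Labels absent from the template get an identity row.
    """
    template = {
        "Standing": {"Standing": 0.96, "Foraging": 0.02, "Drinking": 0.02},
        "Lying down": {"Lying down": 0.98, "Standing": 0.02},
        "Foraging": {"Foraging": 0.90, "Hay-net": 0.06, "Standing": 0.04},
        "Hay-net": {"Hay-net": 0.70, "Foraging": 0.25, "Standing": 0.05},
        "Drinking": {"Drinking": 0.60, "Standing": 0.35, "Foraging": 0.05},
    }
    labels = list(labels)
    C = pd.DataFrame(0.0, index=labels, columns=labels)
    for true in labels:
        row = {k: v for k, v in template.get(true, {}).items() if k in labels}
        if not row or not np.isclose(sum(row.values()), 1.0):
            row = {true: 1.0}
        for pred, p in row.items():
            C.loc[true, pred] = p
    C = C.div(C.sum(axis=1), axis=0)
    return C


def default_noise(config: EthogramConfig) -> NoiseModel:
    labels = _detection_labels(config)
    return NoiseModel(det_confuse=default_confusion(labels))


def _detection_labels(config: EthogramConfig) -> list[str]:
    """Labels a box-based detector emits: zone-ruled behaviors + default.

    Sway is excluded — it is not localizable to a zone and box-based
    detectors code it as the underlying posture (standing).
    """
    ruled = {r.behavior for r in config.zone_rules}
    return [b.name for b in config.behaviors
            if b.name in ruled or b.is_default]


def random_script(
    config: EthogramConfig,
    seed: int,
    mean_bout_s: Mapping[str, float] | None = None,
    total_duration_s: int = NIGHT_S,
) -> SimulationScript:
    """Draw an alternating-renewal night script.

    Behaviors alternate (no immediate repeat, uniform choice among the
    others); bout durations are exponential with the given per-behavior
    mean, clamped to at least 1 s and rounded to whole seconds.  The
    final bout is truncated at the end of the night.  Deterministic for
    a fixed seed.
    """
    means = dict(DEFAULT_MEAN_BOUT_S if mean_bout_s is None else mean_bout_s)
    unknown = set(means) - set(config.behavior_names)
    if unknown:
        raise ValueError(f"mean_bout_s for undeclared behaviors: {sorted(unknown)}")
    if any(m <= 0 for m in means.values()):
        raise ValueError("mean bout durations must be positive")
    names = list(means)
    rng = np.random.default_rng(seed)
    bouts: list[tuple[str, int, int]] = []
    t = 0
    current: str | None = None
    while t < total_duration_s:
        if len(names) == 1:
            current = names[0]
        else:
            choices = [n for n in names if n != current]
            current = choices[rng.integers(len(choices))]
        dur = max(1, int(round(rng.exponential(means[current]))))
        dur = min(dur, total_duration_s - t)
        bouts.append((current, t, dur))
        t += dur
    return SimulationScript(tuple(bouts), total_duration_s, seed)


def rasterize_script(
    script: SimulationScript,
    config: EthogramConfig,
) -> BehaviorSequence:
    """Ground-truth second-resolution sequence implied by a script."""
    labels = np.full(script.total_duration_s, config.default_behavior, dtype=object)
    for name, start, dur in script.bouts:
        labels[start : start + dur] = name
    return BehaviorSequence(labels, "second", config.fps)


def simulate_night(
    script: SimulationScript,
    config: EthogramConfig,
    noise: NoiseModel | None = None,
    seed: int = 0,
    sway: SwayKinematics | None = None,
    sway_bodyparts: Sequence[str] = ("head", "trunk_root"),
) -> tuple[KeypointTrack, DetectionStream, BehaviorSequence]:
    """Render a script into (pose track, detection stream, ground truth).

    All randomness flows from one generator seeded with ``seed``.  With
    ``noise=noiseless()`` the pose track places every constrained body
    part exactly at its behavior's geometry point, so zone
    classification recovers the script perfectly.
    """
    if noise is None:
        noise = default_noise(config)
    if sway is None:
        sway = SwayKinematics()
    rng = np.random.default_rng(seed)

    geometry = config.geometry
    missing_geom = {b for b, _, _ in script.bouts if b not in geometry}
    if missing_geom:
        raise ValueError(f"scripted behaviors lack geometry: {sorted(missing_geom)}")
    if config.default_behavior not in geometry:
        raise ValueError("default behavior lacks geometry (needed for gaps)")

    fps = config.fps
    if abs(fps - round(fps)) > 1e-9:
        raise ValueError("simulation requires an integer FPS")
    fpsi = int(round(fps))
    truth = rasterize_script(script, config)
    n_frames = script.total_duration_s * fpsi
    frame_labels = np.repeat(truth.labels, fpsi)

    names = config.behavior_names
    code_of = {name: i for i, name in enumerate(names)}
    codes = np.fromiter((code_of[l] for l in frame_labels), dtype=np.int64,
                        count=n_frames)

    parts = list(config.bodyparts)
    n_parts = len(parts)
    geom_x = np.zeros((len(names), n_parts))
    geom_y = np.zeros((len(names), n_parts))
    default_xy = geometry[config.default_behavior]
    for bi, bname in enumerate(names):
        placement = geometry.get(bname, default_xy)
        for pj, part in enumerate(parts):
            gx, gy = placement.get(part, default_xy.get(part, (np.nan, np.nan)))
            geom_x[bi, pj] = gx
            geom_y[bi, pj] = gy

    x = geom_x[codes]
    y = geom_y[codes]

    # Sinusoidal lateral sway, phase zero at each bout start.
    sway_cols = [parts.index(p) for p in sway_bodyparts if p in parts]
    if sway_cols:
        for start_s, end_s in script.bouts_of("Swaying"):
            f0, f1 = start_s * fpsi, end_s * fpsi
            t_rel = (np.arange(f1 - f0)) / fps
            dx = sway.amplitude_px * np.sin(2 * np.pi * t_rel / sway.period_s)
            for col in sway_cols:
                x[f0:f1, col] += dx

    if noise.coord_sd > 0:
        x = x + rng.normal(0.0, noise.coord_sd, x.shape)
        y = y + rng.normal(0.0, noise.coord_sd, y.shape)

    likelihood = rng.uniform(0.9, 1.0, x.shape)
    if noise.low_conf_p > 0:
        low = rng.random(x.shape) < noise.low_conf_p
        likelihood[low] = rng.uniform(0.0, config.p_cutoff * 0.999, low.sum())
    if noise.dropout_p > 0:
        drop = rng.random(x.shape) < noise.dropout_p
        x[drop] = np.nan
        y[drop] = np.nan
        likelihood[drop] = np.nan

    track = KeypointTrack(parts, x, y, likelihood, fps)

    # Detection stream: per-frame label drawn from the confusion row of
    # the true behavior (sway reads as its underlying posture: standing).
    det_labels_set = _detection_labels(config)
    C = noise.det_confuse
    if C is None:
        C = pd.DataFrame(np.eye(len(det_labels_set)),
                         index=det_labels_set, columns=det_labels_set)
    else:
        missing = set(det_labels_set) - set(C.index)
        if missing:
            raise ValueError(f"det_confuse lacks rows for {sorted(missing)}")
        C = C.loc[det_labels_set, det_labels_set]
        C = C.div(C.to_numpy().sum(axis=1), axis=0)

    det_code_of = {name: i for i, name in enumerate(det_labels_set)}
    default_code = det_code_of[config.default_behavior]
    det_true = np.fromiter(
        (det_code_of.get(l, default_code) for l in frame_labels),
        dtype=np.int64, count=n_frames,
    )
    cum = np.cumsum(C.to_numpy(), axis=1)
    u = rng.random(n_frames)
    emitted = (u[:, None] > cum[det_true]).sum(axis=1)
    emitted = np.minimum(emitted, len(det_labels_set) - 1)

    det_label_arr = np.array(det_labels_set, dtype=object)[emitted]
    confidence = rng.uniform(0.6, 1.0, n_frames)
    if noise.det_miss_p > 0:
        miss = rng.random(n_frames) < noise.det_miss_p
        det_label_arr[miss] = None
        confidence[miss] = np.nan
    stream = DetectionStream(det_label_arr, confidence, tuple(det_labels_set), fps)

    return track, stream, truth
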