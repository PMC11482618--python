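"""Rule-based behavior classification of pose tracks and detection streams.

The coding procedure mirrors how coordinate-limit classification is done
downstream of a pose-estimation model:

1. condition keypoints on a likelihood p-cutoff (default 0.5);
2. per frame, the lowest-priority zone rule whose constrained body parts
   are all valid and inside their boxes assigns the behavior;
3. frames matching no rule are the default behavior if at least one
   anchor body part is valid, else OUT_OF_VIEW;
4. frame labels are aggregated to seconds by majority vote (matching the
   second-by-second resolution of manual scoring);
5. minimum-duration constraints (e.g. sway >= 5 s) are enforced on the
   second-resolution sequence.

Detection streams (per-frame behavior labels with confidences from an
object-detection model) enter the same pipeline at step 3 via
:func:`detections_to_sequence`.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

from .config import OUT_OF_VIEW, EthogramConfig
from .io import BehaviorSequence, DetectionStream, KeypointTrack

__all__ = [
    "apply_pcutoff",
    "classify_frame",
    "classify_track",
    "detections_to_sequence",
    "aggregate_to_seconds",
    "enforce_min_duration",
]


def apply_pcutoff(track: KeypointTrack, p_cutoff: float) -> KeypointTrack:
    """Invalidate samples with likelihood below the cutoff (or missing).

    Returns a new track where invalid samples are NaN in x, y and
    likelihood; samples at or above the cutoff are unchanged (a value
    exactly equal to the cutoff is retained).
    """
    if not 0.0 <= p_cutoff <= 1.0:
        raise ValueError(f"p_cutoff must be in [0, 1], got {p_cutoff}")
    keep = track.valid_mask(p_cutoff)
    x = np.where(keep, track.x, np.nan)
    y = np.where(keep, track.y, np.nan)
    lk = np.where(keep, track.likelihood, np.nan)
    return KeypointTrack(
        list(track.bodyparts), x, y, lk, track.fps, track.origin_time, track.scorer
    )


def classify_frame(
    keypoints: Mapping[str, tuple[float, float] | None],
    config: EthogramConfig,
) -> str:
    """Classify one frame from already-conditioned keypoint positions.

    ``keypoints`` maps body part name to an (x, y) position, or ``None``
    (or a NaN coordinate) when the sample is invalid.  Positions are
    assumed to already have passed the p-cutoff.
    """
    def valid(part: str) -> bool:
        pos = keypoints.get(part)
        return pos is not None and math.isfinite(pos[0]) and math.isfinite(pos[1])

    for rule in config.rules_by_priority():
        if all(
            valid(c.bodypart) and c.contains(*keypoints[c.bodypart])
            for c in rule.constraints
        ):
            return rule.behavior
    if any(valid(part) for part in config.anchor_bodyparts):
        return config.default_behavior
    return OUT_OF_VIEW


def classify_track(
    track: KeypointTrack,
    config: EthogramConfig,
    p_cutoff: float | None = None,
) -> BehaviorSequence:
    """Classify every frame of a track (frame-resolution output).

    The p-cutoff (``config.p_cutoff`` unless overridden) is applied
    internally, so raw tracks may be passed directly.
    """
    cutoff = config.p_cutoff if p_cutoff is None else p_cutoff
    valid = track.valid_mask(cutoff)  # (n_frames, n_parts)
    n = track.n_frames
    labels = np.full(n, None, dtype=object)

    part_idx = {p: i for i, p in enumerate(track.bodyparts)}
    # Descending priority so later (stronger, lower-numbered) rules overwrite.
    for rule in sorted(config.zone_rules, key=lambda r: -r.priority):
        mask = np.ones(n, dtype=bool)
        for c in rule.constraints:
            if c.bodypart not in part_idx:
                mask[:] = False
                break
            j = part_idx[c.bodypart]
            with np.errstate(invalid="ignore"):
                mask &= (
                    valid[:, j]
                    & (track.x[:, j] >= c.x_min)
                    & (track.x[:, j] <= c.x_max)
                    & (track.y[:, j] >= c.y_min)
                    & (track.y[:, j] <= c.y_max)
                )
        labels[mask] = rule.behavior

    unmatched = labels == None  # noqa: E711
    anchor_cols = [part_idx[p] for p in config.anchor_bodyparts if p in part_idx]
    if anchor_cols:
        in_view = valid[:, anchor_cols].any(axis=1)
    else:
        in_view = np.zeros(n, dtype=bool)
    labels[unmatched & in_view] = config.default_behavior
    labels[unmatched & ~in_view] = OUT_OF_VIEW
    return BehaviorSequence(labels, "frame", track.fps, track.origin_time)


def detections_to_sequence(
    stream: DetectionStream,
    min_confidence: float = 0.0,
) -> BehaviorSequence:
    """Turn a detection stream into a frame-resolution behavior sequence.

    Labeled frames whose confidence is at or above ``min_confidence``
    keep their label; unlabeled or low-confidence frames become
    OUT_OF_VIEW.
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError(f"min_confidence must be in [0, 1], got {min_confidence}")
    with np.errstate(invalid="ignore"):
        keep = np.isfinite(stream.confidence) & (stream.confidence >= min_confidence)
    labels = np.where(keep, stream.labels, OUT_OF_VIEW).astype(object)
    return BehaviorSequence(labels, "frame", stream.fps, stream.origin_time)


def aggregate_to_seconds(
    seq: BehaviorSequence,
    config: EthogramConfig,
) -> BehaviorSequence:
    """Majority-vote a frame-resolution sequence down to seconds.

    Second ``s`` covers frames ``floor(s*fps) .. floor((s+1)*fps) - 1``.
    Ties are broken by the config's tie rank (zone-rule priority first,
    then declaration order); OUT_OF_VIEW loses every tie.
    """
    if seq.resolution != "frame":
        raise ValueError("aggregate_to_seconds expects a frame-resolution sequence")
    fps = seq.fps
    n_frames = seq.n_ticks
    if n_frames == 0:
        return BehaviorSequence(
            np.empty(0, dtype=object), "second", fps, seq.origin_time
        )
    n_seconds = int(np.ceil(n_frames / fps))

    rank = config.tie_rank()
    # Column order = tie rank, so argmax resolves ties toward better rank.
    order = sorted(rank, key=rank.get)
    code_of = {name: i for i, name in enumerate(order)}
    try:
        codes = np.fromiter(
            (code_of[l] for l in seq.labels), dtype=np.int64, count=n_frames
        )
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} not in config label set") from None
    sec_idx = (np.arange(n_frames) / fps).astype(np.int64)
    counts = np.zeros((n_seconds, len(order)), dtype=np.int64)
    np.add.at(counts, (sec_idx, codes), 1)
    winners = np.argmax(counts, axis=1)  # first max = best tie rank
    labels = np.array(order, dtype=object)[winners]
    return BehaviorSequence(labels, "second", fps, seq.origin_time)


def enforce_min_duration(
    seq: BehaviorSequence,
    config: EthogramConfig,
) -> BehaviorSequence:
    """Relabel too-short bouts of duration-constrained behaviors.

    Every maximal run of a behavior with ``min_duration_s > 0`` that is
    shorter than its minimum becomes the default behavior; all other
    labels are untouched.  Operates on second-resolution sequences.
    """
    if seq.resolution != "second":
        raise ValueError("enforce_min_duration expects a second-resolution sequence")
    constrained = {
        b.name: b.min_duration_s for b in config.behaviors if b.min_duration_s > 0
    }
    if not constrained or seq.n_ticks == 0:
        return BehaviorSequence(
            seq.labels.copy(), "second", seq.fps, seq.origin_time
        )
    labels = seq.labels.copy()
    n = len(labels)
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            run_label = labels[start]
            run_len = i - start  # seconds, at 1 s per tick
            if run_label in constrained and run_len < constrained[run_label]:
                labels[start:i] = config.default_behavior
            start = i
    return BehaviorSequence(labels, "second", seq.fps, seq.origin_time)
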