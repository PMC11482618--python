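"""Readers and writers for pose tracks, detection streams and label files.

Three plain-text CSV dialects are supported:

* **Pose CSV** — the pose-estimation export dialect with three header rows
  (scorer, bodyparts, coords) where the coords row cycles
  ``x, y, likelihood`` per body part and the first column is the frame
  index.  Empty cells mean the network produced no label for that
  (frame, body part) — distinct from a low-likelihood label.
* **Detection CSV** — one row per *labeled* frame: ``frame,behavior,
  confidence``; unlisted frames are unlabeled.  Stream metadata
  (``n_frames``, ``fps``, label set) travels in ``# key=value`` comment
  lines so a file is self-describing.
* **Label CSV** — one row per labeled tick (``second,behavior`` or
  ``frame,behavior``); gaps read back as OUT_OF_VIEW.  This is also the
  format of manual second-by-second scoring files.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import OUT_OF_VIEW

__all__ = [
    "KeypointTrack",
    "DetectionStream",
    "BehaviorSequence",
    "ParseError",
    "read_pose_csv",
    "write_pose_csv",
    "read_detections_csv",
    "write_detections_csv",
    "read_labels_csv",
    "write_labels_csv",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending row/column."""


def _meta_header(**kv) -> str:
    return "# " + " ".join(f"{k}={v}" for k, v in kv.items()) + "\n"


def _read_meta(line: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for token in line.lstrip("#").split():
        if "=" in token:
            k, _, v = token.partition("=")
            out[k] = v
    return out


@dataclass
class KeypointTrack:
    """Rectangular grid of (x, y, likelihood) per frame and body part.

    Missing samples (unlabeled by the network) are NaN in all three
    arrays.  Arrays have shape ``(n_frames, n_bodyparts)``.
    """

    bodyparts: list[str]
    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    fps: float = 25.0
    origin_time: str = "22:00:00"
    scorer: str = "ethotrace"

    def __post_init__(self) -> None:
        n_parts = len(self.bodyparts)
        for name in ("x", "y", "likelihood"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != n_parts:
                raise ValueError(
                    f"{name} must have shape (n_frames, {n_parts}), got {arr.shape}"
                )
            setattr(self, name, arr)
        lk = self.likelihood
        bad = np.isfinite(lk) & ((lk < 0) | (lk > 1))
        if bad.any():
            fr, bp = np.argwhere(bad)[0]
            raise ValueError(
                f"likelihood outside [0, 1] at frame {fr}, "
                f"bodypart {self.bodyparts[bp]!r}: {lk[fr, bp]}"
            )

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def part_index(self, bodypart: str) -> int:
        try:
            return self.bodyparts.index(bodypart)
        except ValueError:
            raise KeyError(f"bodypart {bodypart!r} not in track") from None

    def valid_mask(self, p_cutoff: float | None = None) -> np.ndarray:
        """Boolean (n_frames, n_parts): labeled, and above cutoff if given.

        A likelihood exactly equal to the cutoff is retained (closed
        lower bound).
        """
        ok = (
            np.isfinite(self.x)
            & np.isfinite(self.y)
            & np.isfinite(self.likelihood)
        )
        if p_cutoff is not None:
            ok &= self.likelihood >= p_cutoff
        return ok

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KeypointTrack):
            return NotImplemented
        return (
            self.bodyparts == other.bodyparts
            and self.fps == other.fps
            and self.origin_time == other.origin_time
            and all(
                np.array_equal(getattr(self, a), getattr(other, a), equal_nan=True)
                for a in ("x", "y", "likelihood")
            )
        )


@dataclass
class DetectionStream:
    """Per-frame object-detection output: optional (label, confidence).

    ``labels`` is an object array with ``None`` for unlabeled frames;
    ``confidence`` is NaN exactly where the label is ``None``.
    """

    labels: np.ndarray
    confidence: np.ndarray
    label_set: tuple[str, ...]
    fps: float = 25.0
    origin_time: str = "22:00:00"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.labels.shape != self.confidence.shape:
            raise ValueError("labels and confidence must have equal length")
        labeled = self.labels != None  # noqa: E711 — elementwise on object array
        if np.any(labeled != np.isfinite(self.confidence)):
            raise ValueError("confidence must be present iff a label is present")
        unknown = {l for l in self.labels[labeled] if l not in self.label_set}
        if unknown:
            raise ValueError(f"labels outside declared label set: {sorted(unknown)}")

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DetectionStream):
            return NotImplemented
        return (
            tuple(self.label_set) == tuple(other.label_set)
            and self.fps == other.fps
            and self.origin_time == other.origin_time
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.confidence, other.confidence, equal_nan=True)
        )


@dataclass
class BehaviorSequence:
    """Fully labeled behavior timeline at frame or second resolution.

    Every tick carries a label; OUT_OF_VIEW fills time with no observed
    or classified behavior, so total duration is always ``n_ticks / rate``.
    """

    labels: np.ndarray
    resolution: str = "second"  # "frame" | "second"
    fps: float = 25.0
    origin_time: str = "22:00:00"

    def __post_init__(self) -> None:
        if self.resolution not in ("frame", "second"):
            raise ValueError(f"resolution must be frame|second, got {self.resolution!r}")
        self.labels = np.asarray(self.labels, dtype=object)
        if any(l is None for l in self.labels):
            raise ValueError("every tick must be labeled (use OUT_OF_VIEW)")

    @property
    def rate(self) -> float:
        return self.fps if self.resolution == "frame" else 1.0

    @property
    def n_ticks(self) -> int:
        return self.labels.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_ticks / self.rate

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BehaviorSequence):
            return NotImplemented
        return (
            self.resolution == other.resolution
            and self.fps == other.fps
            and self.origin_time == other.origin_time
            and np.array_equal(self.labels, other.labels)
        )


# -- pose CSV ------------------------------------------------------------

def read_pose_csv(path: str | Path, fps: float = 25.0,
                  origin_time: str = "22:00:00") -> KeypointTrack:
    """Read the 3-header-row pose CSV dialect into a KeypointTrack."""
    try:
        head = pd.read_csv(path, header=None, nrows=3)
    except Exception as exc:
        raise ParseError(f"{path}: cannot read header rows: {exc}") from exc
    if head.shape[0] < 3 or str(head.iat[2, 0]).strip().lower() != "coords":
        raise ParseError(f"{path}: expected 3 header rows (scorer/bodyparts/coords)")
    scorer = str(head.iat[0, 1]) if head.shape[1] > 1 else "unknown"
    part_row = [str(v) for v in head.iloc[1, 1:]]
    coord_row = [str(v).strip().lower() for v in head.iloc[2, 1:]]
    if len(coord_row) % 3 != 0:
        raise ParseError(f"{path}: data columns not a multiple of 3")
    bodyparts: list[str] = []
    for i in range(0, len(coord_row), 3):
        if coord_row[i : i + 3] != ["x", "y", "likelihood"]:
            raise ParseError(
                f"{path}: header triplet at column {i + 1} is "
                f"{coord_row[i:i + 3]}, expected ['x', 'y', 'likelihood']"
            )
        if len(set(part_row[i : i + 3])) != 1:
            raise ParseError(
                f"{path}: bodyparts row disagrees within triplet at column {i + 1}"
            )
        bodyparts.append(part_row[i])

    try:
        body = pd.read_csv(path, skiprows=3, header=None,
                           float_precision="round_trip")
    except pd.errors.EmptyDataError:
        body = pd.DataFrame()
    if body.shape[1] != 1 + 3 * len(bodyparts) and body.shape[0] > 0:
        raise ParseError(f"{path}: data rows have wrong column count")
    n = body.shape[0]
    if n == 0:
        z = np.zeros((0, len(bodyparts)))
        return KeypointTrack(bodyparts, z, z.copy(), z.copy(), fps, origin_time, scorer)
    data = np.full((n, 3 * len(bodyparts)), np.nan)
    for j in range(3 * len(bodyparts)):
        col = pd.to_numeric(body.iloc[:, j + 1], errors="coerce")
        raw = body.iloc[:, j + 1]
        bad = col.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric cell at data row {row}, column {j + 1}: "
                f"{raw.iloc[row]!r}"
            )
        data[:, j] = col.to_numpy()
    x = data[:, 0::3]
    y = data[:, 1::3]
    lk = data[:, 2::3]
    bad_lk = np.isfinite(lk) & ((lk < 0) | (lk > 1))
    if bad_lk.any():
        fr, bp = np.argwhere(bad_lk)[0]
        raise ParseError(
            f"{path}: likelihood outside [0, 1] at data row {fr}, "
            f"bodypart {bodyparts[bp]!r}: {lk[fr, bp]}"
        )
    # any NaN in a triplet makes the whole sample missing
    missing = ~(np.isfinite(x) & np.isfinite(y) & np.isfinite(lk))
    x[missing] = np.nan
    y[missing] = np.nan
    lk[missing] = np.nan
    return KeypointTrack(bodyparts, x, y, lk, fps, origin_time, scorer)


def write_pose_csv(track: KeypointTrack, path: str | Path) -> None:
    """Write a KeypointTrack in the 3-header-row pose CSV dialect."""
    n_parts = len(track.bodyparts)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["scorer"] + [track.scorer] * (3 * n_parts))
        w.writerow(["bodyparts"] + [p for p in track.bodyparts for _ in range(3)])
        w.writerow(["coords"] + ["x", "y", "likelihood"] * n_parts)
        for fr in range(track.n_frames):
            row: list[object] = [fr]
            for j in range(n_parts):
                vals = (track.x[fr, j], track.y[fr, j], track.likelihood[fr, j])
                row.extend("" if not np.isfinite(v) else repr(float(v)) for v in vals)
            w.writerow(row)


# -- detection CSV -------------------------------------------------------

def read_detections_csv(path: str | Path,
                        n_frames: int | None = None,
                        label_set: Sequence[str] | None = None) -> DetectionStream:
    """Read a detection CSV; unlisted frames become unlabeled.

    ``n_frames`` and ``label_set`` default to the file's ``#`` metadata
    header; passing them explicitly overrides it.
    """
    meta: dict[str, str] = {}
    rows: list[tuple[int, str, float]] = []
    with open(path) as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row:
                continue
            if row[0].startswith("#"):
                meta.update(_read_meta(",".join(row)))
                continue
            if row[0].strip().lower() == "frame":
                continue
            if len(row) < 2:
                raise ParseError(f"{path}:{lineno}: expected frame,behavior[,confidence]")
            try:
                frame = int(row[0])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad frame index {row[0]!r}") from None
            conf = 1.0
            if len(row) > 2 and row[2].strip():
                try:
                    conf = float(row[2])
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: bad confidence {row[2]!r}"
                    ) from None
            rows.append((frame, row[1], conf))

    if n_frames is None:
        if "n_frames" not in meta:
            raise ParseError(f"{path}: n_frames neither passed nor in metadata header")
        n_frames = int(meta["n_frames"])
    fps = float(meta.get("fps", 25.0))
    origin = meta.get("origin", "22:00:00")
    if label_set is None:
        if "labels" in meta:
            label_set = tuple(meta["labels"].split("|"))
        else:
            label_set = tuple(sorted({r[1] for r in rows}))

    labels = np.full(n_frames, None, dtype=object)
    conf = np.full(n_frames, np.nan)
    seen: set[int] = set()
    for frame, label, c in rows:
        if frame in seen:
            raise ParseError(f"{path}: duplicate detection for frame {frame}")
        seen.add(frame)
        if not 0 <= frame < n_frames:
            raise ParseError(f"{path}: frame {frame} outside 0..{n_frames - 1}")
        if label not in label_set:
            raise ParseError(f"{path}: unknown label {label!r} at frame {frame}")
        labels[frame] = label
        conf[frame] = c
    return DetectionStream(labels, conf, tuple(label_set), fps, origin)


def write_detections_csv(stream: DetectionStream, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(
            _meta_header(
                n_frames=stream.n_frames,
                fps=stream.fps,
                origin=stream.origin_time,
                labels="|".join(stream.label_set),
            )
        )
        w = csv.writer(fh)
        w.writerow(["frame", "behavior", "confidence"])
        for fr in np.flatnonzero(stream.labels != None):  # noqa: E711
            w.writerow([int(fr), stream.labels[fr], repr(float(stream.confidence[fr]))])


# -- label CSV (behavior sequences, incl. manual scoring) ----------------

def read_labels_csv(path: str | Path,
                    n_ticks: int | None = None,
                    resolution: str | None = None) -> BehaviorSequence:
    """Read a label CSV; ticks absent from the file become OUT_OF_VIEW."""
    meta: dict[str, str] = {}
    rows: list[tuple[int, str]] = []
    with open(path) as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row:
                continue
            if row[0].startswith("#"):
                meta.update(_read_meta(",".join(row)))
                continue
            if row[0].strip().lower() in ("second", "frame", "tick"):
                continue
            if len(row) < 2:
                raise ParseError(f"{path}:{lineno}: expected tick,behavior")
            try:
                tick = int(row[0])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad tick index {row[0]!r}") from None
            rows.append((tick, row[1]))
    if resolution is None:
        resolution = meta.get("resolution", "second")
    if n_ticks is None:
        if "n" in meta:
            n_ticks = int(meta["n"])
        elif rows:
            n_ticks = max(t for t, _ in rows) + 1
        else:
            raise ParseError(f"{path}: n neither passed nor in metadata header")
    fps = float(meta.get("fps", 25.0))
    origin = meta.get("origin", "22:00:00")
    labels = np.full(n_ticks, OUT_OF_VIEW, dtype=object)
    seen: set[int] = set()
    for tick, label in rows:
        if tick in seen:
            raise ParseError(f"{path}: duplicate label for tick {tick}")
        seen.add(tick)
        if not 0 <= tick < n_ticks:
            raise ParseError(f"{path}: tick {tick} outside 0..{n_ticks - 1}")
        labels[tick] = label
    return BehaviorSequence(labels, resolution, fps, origin)


def write_labels_csv(seq: BehaviorSequence, path: str | Path) -> None:
    tick_name = "second" if seq.resolution == "second" else "frame"
    with open(path, "w", newline="") as fh:
        fh.write(
            _meta_header(
                resolution=seq.resolution,
                n=seq.n_ticks,
                fps=seq.fps,
                origin=seq.origin_time,
            )
        )
        w = csv.writer(fh)
        w.writerow([tick_name, "behavior"])
        for t in range(seq.n_ticks):
            if seq.labels[t] != OUT_OF_VIEW:
                w.writerow([t, seq.labels[t]])
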